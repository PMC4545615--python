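# Photon interaction coefficients, version 1.
#
# Mass attenuation coefficients (cm^2/g, coherent scattering excluded from
# transport and folded out) and photoelectric interaction fractions on a
# common energy grid, for the three voxel material classes.  Values are
# compiled from standard photon cross-section tabulations (NIST XCOM-style)
# for liquid water (used for both soft tissue and lung, whose elemental
# compositions are near-identical; density differences are applied per voxel)
# and ICRU-44 cortical bone, rounded to the precision shown.
#
# pe_fraction = photoelectric / (photoelectric + incoherent) at each energy;
# the remainder is Compton scattering.  The transport cutoff (default 20 keV)
# keeps photons inside the tabulated grid.

energy_MeV: [0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.10, 0.15, 0.20, 0.30, 0.50]

soft_tissue:
  mu_over_rho_cm2_g: [0.7700, 0.3575, 0.2580, 0.2190, 0.2000, 0.1795, 0.1675, 0.1480, 0.1350, 0.1175, 0.0965]
  pe_fraction:       [0.400,  0.244,  0.150,  0.090,  0.057,  0.026,  0.0160, 0.0053, 0.0027, 0.0010, 0.0004]

lung:
  mu_over_rho_cm2_g: [0.7700, 0.3575, 0.2580, 0.2190, 0.2000, 0.1795, 0.1675, 0.1480, 0.1350, 0.1175, 0.0965]
  pe_fraction:       [0.400,  0.244,  0.150,  0.090,  0.057,  0.026,  0.0160, 0.0053, 0.0027, 0.0010, 0.0004]

bone:
  mu_over_rho_cm2_g: [3.8500, 1.2800, 0.6400, 0.4100, 0.3050, 0.2170, 0.1810, 0.1450, 0.1285, 0.1095, 0.0895]
  pe_fraction:       [0.890,  0.780,  0.630,  0.470,  0.340,  0.180,  0.1050, 0.0370, 0.0170, 0.0060, 0.0020]
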