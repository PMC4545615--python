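# Bundled radionuclide decay data, version 1.
#
# Energies in MeV, yields per decay.  Values compiled from the standard
# MIRD / ICRP Publication 107 decay data compendia, rounded to the precision
# shown.  Half-lives follow the conventional values 6.71 d (177Lu) and
# 2.66 d (90Y) used throughout this package's matched-pair arithmetic.
#
# 177Lu: the two listed gamma lines are the imaging photopeaks (113 and
# 208 keV); minor lines below 1% yield and characteristic x-rays are folded
# into the transport as negligible and omitted.  The beta emission is carried
# as a mean energy per decay (sub-voxel range at ~4.8 mm voxels, transported
# by local deposition).
#
# 90Y: pure beta emitter; endpoint 2.2801 MeV, mean 0.9337 MeV per decay.
# The long beta range requires kernel transport; the radial kernel is derived
# at run time from an allowed-shape spectrum with this endpoint.

lu177:
  name: Lu-177
  half_life_h: 161.04          # 6.71 d
  photon_lines:
    - [0.11295, 0.0617]        # 113 keV line
    - [0.20837, 0.1036]        # 208 keV line
  beta_mean_energy_MeV: 0.1335
  beta_yield: 1.0
  beta_transport: local

y90:
  name: Y-90
  half_life_h: 63.84           # 2.66 d
  photon_lines: []
  beta_mean_energy_MeV: 0.9337
  beta_yield: 1.0
  beta_max_energy_MeV: 2.2801
  beta_transport: kernel
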