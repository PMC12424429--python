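# Built-in simulation presets.
#
# Each preset reverse-engineers the generative parameters of one
# experimental condition from its published summary statistics: the free
# diffusion coefficient is the condition's median D_200ms of the mobile
# population, the trap dwell mean is the mean detected trapping duration
# minus the 5-frame threshold time (memoryless truncation), and the
# occupancy is the detected temporal fraction divided by the length-bias
# factor e^(-T/tau)(1 + T/tau).  Presets are for validation by parameter
# recovery, not biological claims.

wt_pre:
  comment: "KRAS WT-like, serum-starved (pre-stimulation)"
  d_free: 0.53
  trap_conf_sd: 10.0
  trap_dwell_mean: 0.0723     # 239 ms mean detected duration - 166.7 ms
  occupancy: 0.1031           # detected temporal fraction 3.4%
  sigma_axis: 14.0
  bleach_lifetime: 10.4

wt_post2:
  comment: "KRAS WT-like, 2 min after EGF stimulation (trapping peak)"
  d_free: 0.45
  trap_conf_sd: 10.0
  trap_dwell_mean: 0.1713     # 338 ms mean detected duration - 166.7 ms
  occupancy: 0.1086           # detected temporal fraction 8.1%
  sigma_axis: 14.0
  bleach_lifetime: 10.4

mutant_g12v:
  comment: "constitutively active KRAS mutant-like (elevated baseline trapping)"
  d_free: 0.45
  trap_conf_sd: 10.0
  trap_dwell_mean: 0.1133     # ~280 ms mean detected duration - 166.7 ms
  occupancy: 0.1409           # detected temporal fraction 8.0%
  sigma_axis: 14.0
  bleach_lifetime: 10.4

sos1:
  comment: "SOS1-like: slow diffusion, high trapping occupancy"
  d_free: 0.1
  trap_conf_sd: 10.0
  trap_dwell_mean: 0.1413     # 308 ms mean detected duration - 166.7 ms
  occupancy: 0.6865           # detected temporal fraction 46%
  sigma_axis: 14.0
  bleach_lifetime: 10.4

braf:
  comment: "BRAF-like: slow diffusion, intermediate occupancy, red channel"
  d_free: 0.1
  trap_conf_sd: 10.0
  trap_dwell_mean: 0.1613     # 328 ms mean detected duration - 166.7 ms
  occupancy: 0.3179           # detected temporal fraction 23%
  sigma_axis: 18.7
  channel: "red"
  bleach_lifetime: 8.1

immobile_reference:
  comment: "stationary emitters (glass-immobilized reference for threshold calibration)"
  d_free: 0.0
  trap_conf_sd: 0.0
  trap_dwell_mean: 1.0
  occupancy: 1.0
  sigma_axis: 14.0
  bleach_lifetime: 10.4
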