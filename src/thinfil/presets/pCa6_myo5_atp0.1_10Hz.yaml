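# pCa6_myo5_atp0.1_10Hz: [Myo]=5 nM, [ATP]=0.1 uM, pCa 6, 10 Hz, 1000 frames
condition:
  myo_nM: 5
  atp_uM: 0.1
  pCa: 6
  epsilon: 0.06
  C: 70
  frame_rate_hz: 10
  n_frames: 1000
  sigma_N: 0.25
  t_equil_s: 35.0
  length_um: 3.0
  spacing_nm: 5.5
kinetics:
  k_b0: 0.00055
  k_D: 350.0
  k_T: 2.0
optics:
  e: 450.0
  sigma_gfp_nm: 160.0
  pixel_nm: 80.0
  sigma_F: 0.22
  margin_px: 5
replicates: 5
seed: 0
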