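mean:
  base_radius_nm: 30.0
  n_spikes: 10
  spike_amplitude: 0.25
  spike_sharpness: 0.35
  angular_jitter: 0.02
  roughness: 0.01
cv:
  base_radius_nm: 0.05
  spike_amplitude: 0.10
  spike_sharpness: 0.10
n_particles: 200
seed: 0
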