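# Example configuration for `pawcal simulate --config examples/run_config.yaml --out scratch/run`
treatments:
  - label: DBD_12kHz_3min
    source: DBD
    frequency_khz: 12
    activation_time: 180
    Pin: 8.0
  - label: DBD_20kHz_3min
    source: DBD
    frequency_khz: 20
    activation_time: 180
    Pin: 12.0
  - label: DBD_20kHz_30min
    source: DBD
    frequency_khz: 20
    activation_time: 1800
    Pin: 12.0
replicates: 6
seed: 11
window: 1800.0       # 30 min AUC
alpha: 0.05
temp_noise_sd: 0.1   # K
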