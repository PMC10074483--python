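# Desk-scale pipeline configuration: control vs LPS, 5 slices per arm.
# Runs the event-level pipeline (render: false) at the full 40 min protocol.
conditions:
  - 0mg_4ap
  - lps_0mg_4ap
geometry: desk          # 16 x 16 electrodes at 1 kHz
effect_preset: paper    # protocol-scale effect model (SE minimum 300 s)
effect_overrides: {}
detector: {}            # +/-200 uV, 40 ms window, 5 ms refractory, 500 ms cap
classifier: {}
activity:
  min_size: 4
  percentile: 75.0
windows:
  T1: [0.0, 600.0]
  T2: [1200.0, 1800.0]
contrasts:
  - name: lps_effect
    a: lps_0mg_4ap
    b: 0mg_4ap
n_slices: 5
seed: 1
ictogenic_duration: 2400.0
render: false
out_dir: epimea_out
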