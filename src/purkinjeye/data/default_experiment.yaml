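# Default experiment: 9 synthetic subjects, both LED-array configurations,
# the standard protocol (4 -> 1 D in 0.5 D steps, 2 s per LED at 50 Hz)
# and the Purkinje-only ML input subset.  Seeds are mandatory.
schema: purkinjeye/experiment/v1
seed: 1
scene_file: null          # null -> packaged default scene
eye_parameter_file: null  # null -> packaged schematic-eye defaults
cohort:
  n: 9
  anatomy_sd: 0.03
  feature_noise_px: 0.3
  blink_prob: 0.01
protocol:
  dwell_s: 2.0
  frame_rate_hz: 50.0
  ordering: sequential
configurations: [combined, accommodation]
ml:
  subset: purkinje
  leak_free: false
output_dir: purkinjeye-out
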