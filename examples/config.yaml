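# Desk-scale pipeline configuration: 18 subjects (16 train / 2 held out),
# all 13 classes, 2 recordings per class per subject, 4 windows per recording.
seed: 0
synthesis:
  n_subjects: 18
  n_test_subjects: 2
  reps_per_class: 2
  fs: 333.0
  duration: 4.5
  jitter_lo: 0.0
  jitter_hi: 0.03
dsp:
  hr_band: [5.0, 25.0]
  rr_band: [0.1, 0.7]
windowing:
  n_sequences: 4
  length: 1000
training:
  epochs: 20
  iLR: 0.01
  schedule_mode: cosine_annealing
  reduce_to_4: false
  adapt_epochs: 50
  protocol: within_subject
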