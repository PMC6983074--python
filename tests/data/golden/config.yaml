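# reduced golden-run configuration: 9-point grid, 4 frames per point
protocol: train_grid
screen_size: [1920.0, 1080.0]
frames_per_point: 4
gaze_model:
  landmark_noise_sd: 0.5
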