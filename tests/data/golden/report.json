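{
  "avg_error_x": 152.75249107989094,
  "avg_error_y": 18.191750691490952,
  "mean_error_distance": 158.0239009781867
}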