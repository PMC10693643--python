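# desk-scale demonstration settings: small genome, few samples
genome:
  sequence_length: 1000000.0
  samples_per_pop: 10
error:
  error_rate: 0.001
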