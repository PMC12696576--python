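# RCADS-47 item -> subscale assignment (standard scoring key).
# Editable: any partition of items 1-47 into the six subscales is accepted
# by the loader; subscale sizes here are MDD=10, GAD=6, OCD=6, PD=9,
# SAD=7, SP=9.
levels: [0, 1, 2, 3]
subscales:
  SAD: [5, 9, 17, 18, 33, 45, 46]
  GAD: [1, 13, 22, 27, 35, 37]
  PD: [3, 14, 24, 26, 28, 34, 36, 39, 41]
  SP: [4, 7, 8, 12, 20, 30, 32, 38, 43]
  OCD: [10, 16, 23, 31, 42, 44]
  MDD: [2, 6, 11, 15, 19, 21, 25, 29, 40, 47]
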