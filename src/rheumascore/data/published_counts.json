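{
 "dataset_A": {
  "outcome_label": "arthritis development",
  "threshold1": {
   "tp": 14,
   "fn": 7,
   "fp": 8,
   "tn": 21
  },
  "threshold2": {
   "tp": 1,
   "fn": 20,
   "fp": 0,
   "tn": 29
  }
 },
 "dataset_B": {
  "outcome_label": "immune-mediated rheumatic disease",
  "threshold1": {
   "tp": 17,
   "fn": 11,
   "fp": 3,
   "tn": 20
  },
  "threshold2": {
   "tp": 2,
   "fn": 26,
   "fp": 1,
   "tn": 22
  }
 },
 "dataset_C": {
  "outcome_label": "immune-mediated rheumatic disease",
  "threshold1": {
   "tp": 34,
   "fn": 17,
   "fp": 17,
   "tn": 5
  },
  "threshold2": {
   "tp": 7,
   "fn": 44,
   "fp": 2,
   "tn": 20
  }
 }
}
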