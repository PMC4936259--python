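{
 "block_columns": [
  [
   20,
   55
  ],
  [
   75,
   100
  ],
  [
   115,
   145
  ]
 ],
 "corrupted": [
  [
   "sub0_seq1",
   20,
   55
  ],
  [
   "sub0_seq2",
   115,
   145
  ]
 ],
 "related_ids": [
  "query",
  "sub0_seq1",
  "sub0_seq2",
  "sub0_seq3",
  "sub0_seq4",
  "sub0_seq5",
  "sub1_seq0",
  "sub1_seq1",
  "sub1_seq2",
  "sub1_seq3",
  "sub1_seq4",
  "sub1_seq5",
  "sub2_seq0",
  "sub2_seq1",
  "sub2_seq2",
  "sub2_seq3",
  "sub2_seq4",
  "sub2_seq5"
 ],
 "shared_block_columns": [
  [
   20,
   55
  ],
  [
   115,
   145
  ]
 ],
 "subfamily_of": {
  "query": 0,
  "sub0_seq1": 0,
  "sub0_seq2": 0,
  "sub0_seq3": 0,
  "sub0_seq4": 0,
  "sub0_seq5": 0,
  "sub1_seq0": 1,
  "sub1_seq1": 1,
  "sub1_seq2": 1,
  "sub1_seq3": 1,
  "sub1_seq4": 1,
  "sub1_seq5": 1,
  "sub2_seq0": 2,
  "sub2_seq1": 2,
  "sub2_seq2": 2,
  "sub2_seq3": 2,
  "sub2_seq4": 2,
  "sub2_seq5": 2
 },
 "unrelated_ids": [
  "unrelated0",
  "unrelated1",
  "unrelated2",
  "unrelated3"
 ]
}
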