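{
 "node_ids": [
  "g00",
  "g01",
  "g02",
  "g03",
  "g04",
  "g05",
  "g06",
  "g07",
  "g08",
  "g09",
  "g10"
 ],
 "edges": [
  [
   1,
   0,
   1,
   3.111662
  ],
  [
   2,
   1,
   1,
   3.111662
  ],
  [
   3,
   2,
   1,
   3.111662
  ],
  [
   0,
   3,
   1,
   3.111662
  ],
  [
   2,
   0,
   1,
   3.111662
  ],
  [
   3,
   1,
   1,
   3.111662
  ],
  [
   0,
   2,
   1,
   3.111662
  ],
  [
   1,
   3,
   1,
   3.111662
  ],
  [
   4,
   0,
   1,
   1.0
  ],
  [
   5,
   1,
   -1,
   1.0
  ],
  [
   6,
   2,
   1,
   1.0
  ],
  [
   7,
   3,
   1,
   1.0
  ],
  [
   8,
   0,
   -1,
   1.0
  ],
  [
   5,
   4,
   1,
   1.0
  ],
  [
   6,
   5,
   -1,
   1.0
  ],
  [
   7,
   6,
   1,
   1.0
  ],
  [
   8,
   7,
   1,
   1.0
  ],
  [
   9,
   8,
   1,
   1.0
  ],
  [
   10,
   9,
   -1,
   1.0
  ],
  [
   4,
   10,
   1,
   1.0
  ],
  [
   9,
   5,
   1,
   1.0
  ],
  [
   10,
   6,
   1,
   1.0
  ],
  [
   4,
   7,
   -1,
   1.0
  ],
  [
   8,
   10,
   1,
   1.0
  ]
 ],
 "x_star": [
  3.410885,
  2.30936,
  1.622921,
  1.549583,
  3.939811,
  4.238267,
  3.319907,
  3.68849,
  3.130875,
  4.305217,
  3.947561
 ],
 "hill_n": 2.0,
 "hill_k": 3.0,
 "critical_value": 0.0
}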