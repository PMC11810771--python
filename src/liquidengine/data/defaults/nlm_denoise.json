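{
 "method_id": "nlm_denoise",
 "entries": [
  {
   "signature": [
    200.0,
    200.0,
    5.0,
    10.0,
    1.0,
    0.1
   ],
   "times": {
    "unthreaded": [
     0.14755050200005826,
     0.1381831510000211
    ],
    "threaded": [
     0.2631334700000707,
     0.2576107280000315
    ],
    "vectorized": [
     0.25562034300003234,
     0.25299120400006814
    ]
   }
  },
  {
   "signature": [
    200.0,
    200.0,
    10.0,
    10.0,
    1.0,
    0.1
   ],
   "times": {
    "unthreaded": [
     0.14875646699999834,
     0.14728511800001343
    ],
    "threaded": [
     0.26231221700004426,
     0.27149090600005366
    ],
    "vectorized": [
     0.25700934700000744,
     0.2730848989999686
    ]
   }
  },
  {
   "signature": [
    200.0,
    200.0,
    20.0,
    10.0,
    1.0,
    0.1
   ],
   "times": {
    "unthreaded": [
     0.14525618199991186,
     0.1428834520000919
    ],
    "threaded": [
     0.25710840700003246,
     0.26657293999994636
    ],
    "vectorized": [
     0.26220555500003684,
     0.22729049500003384
    ]
   }
  },
  {
   "signature": [
    200.0,
    200.0,
    5.0,
    100.0,
    1.0,
    0.1
   ],
   "times": {
    "unthreaded": [
     5.479085688000055,
     6.818024813999955
    ],
    "threaded": [
     17.683381578999843,
     17.635141753000198
    ],
    "vectorized": [
     16.53337826699999,
     16.32574346399997
    ]
   }
  },
  {
   "signature": [
    200.0,
    200.0,
    10.0,
    100.0,
    1.0,
    0.1
   ],
   "times": {
    "unthreaded": [
     5.492267057999925,
     5.24625316699985
    ],
    "threaded": [
     17.630989653000142,
     17.75569981500007
    ],
    "vectorized": [
     17.37689275699995,
     18.338062919000095
    ]
   }
  },
  {
   "signature": [
    200.0,
    200.0,
    20.0,
    100.0,
    1.0,
    0.1
   ],
   "times": {
    "unthreaded": [
     5.742644839999912,
     7.749011925999866
    ],
    "threaded": [
     19.61816543300006,
     18.890149329999986
    ],
    "vectorized": [
     18.130861779000043,
     17.93253240199988
    ]
   }
  },
  {
   "signature": [
    500.0,
    500.0,
    5.0,
    10.0,
    1.0,
    0.1
   ],
   "times": {
    "unthreaded": [
     0.6939402230000269,
     0.6898507280000103
    ],
    "threaded": [
     1.4558751629999733,
     1.3536215700000866
    ],
    "vectorized": [
     1.2376029819999985,
     1.2541371899999376
    ]
   }
  },
  {
   "signature": [
    500.0,
    500.0,
    10.0,
    10.0,
    1.0,
    0.1
   ],
   "times": {
    "unthreaded": [
     0.8021071380001104,
     0.7483539300001212
    ],
    "threaded": [
     1.477273820999926,
     1.512063094000041
    ],
    "vectorized": [
     1.3179271589999644,
     1.323246908999863
    ]
   }
  },
  {
   "signature": [
    500.0,
    500.0,
    20.0,
    10.0,
    1.0,
    0.1
   ],
   "times": {
    "unthreaded": [
     0.7404874620001465,
     0.8183242090001386
    ],
    "threaded": [
     1.5226556390000496,
     1.7110958880000453
    ],
    "vectorized": [
     1.4801887070000248,
     1.3914447269999073
    ]
   }
  },
  {
   "signature": [
    500.0,
    500.0,
    5.0,
    100.0,
    1.0,
    0.1
   ],
   "times": {
    "unthreaded": [
     66.97219671700009,
     59.76550774500015
    ],
    "threaded": [
     157.57058619500003,
     154.5284246399999
    ],
    "vectorized": [
     120.44854268899985,
     115.54277648100015
    ]
   }
  },
  {
   "signature": [
    500.0,
    500.0,
    10.0,
    100.0,
    1.0,
    0.1
   ],
   "times": {
    "unthreaded": [
     79.28399789200012,
     67.04838350900013
    ],
    "threaded": [
     157.03111974499961,
     122.48820674099989
    ],
    "vectorized": [
     116.91034929700027,
     116.45419379899977
    ]
   }
  },
  {
   "signature": [
    500.0,
    500.0,
    20.0,
    100.0,
    1.0,
    0.1
   ],
   "times": {
    "unthreaded": [
     59.6899030149998,
     58.31355401000019
    ],
    "threaded": [
     122.25435551600003,
     121.44598924000002
    ],
    "vectorized": [
     113.67778597400002,
     111.34144412500018
    ]
   }
  }
 ]
}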