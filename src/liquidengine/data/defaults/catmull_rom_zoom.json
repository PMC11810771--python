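{
 "method_id": "catmull_rom_zoom",
 "entries": [
  {
   "signature": [
    1.0,
    10.0,
    10.0,
    5.0
   ],
   "times": {
    "unthreaded": [
     0.004183857000043645,
     5.8090000038646394e-05
    ],
    "threaded": [
     0.00348768799995014,
     0.000677552999945874
    ],
    "vectorized": [
     0.0003667329999643698,
     0.0004096190000382194
    ]
   }
  },
  {
   "signature": [
    10.0,
    10.0,
    10.0,
    5.0
   ],
   "times": {
    "unthreaded": [
     0.00044635300002937583,
     0.0004342209999776969
    ],
    "threaded": [
     0.00540004599997701,
     0.005793885000002774
    ],
    "vectorized": [
     0.0023101299999552793,
     0.0024055669999825113
    ]
   }
  },
  {
   "signature": [
    10.0,
    100.0,
    100.0,
    5.0
   ],
   "times": {
    "unthreaded": [
     0.04792599000006703,
     0.04532635999999002
    ],
    "threaded": [
     0.16465194800002791,
     0.17113085799996952
    ],
    "vectorized": [
     0.16314936599997054,
     0.17855769100003727
    ]
   }
  },
  {
   "signature": [
    10.0,
    300.0,
    300.0,
    5.0
   ],
   "times": {
    "unthreaded": [
     1.7491471959999672,
     0.4754416370000172
    ],
    "threaded": [
     2.5139658880000297,
     1.9765124770000284
    ],
    "vectorized": [
     2.4544454420000648,
     2.0909304769999153
    ]
   }
  }
 ]
}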