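{
 "method_id": "conv2d",
 "entries": [
  {
   "signature": [
    100.0,
    100.0,
    1.0
   ],
   "times": {
    "unthreaded": [
     0.17377272099997754,
     7.72289999986242e-05
    ],
    "threaded": [
     0.001006576000008863,
     0.0008327570000119522
    ],
    "vectorized": [
     0.0001593000000639222,
     8.11359999488559e-05
    ]
   }
  },
  {
   "signature": [
    100.0,
    100.0,
    5.0
   ],
   "times": {
    "unthreaded": [
     0.0004396650000444424,
     0.00044387200000528537
    ],
    "threaded": [
     0.0013999789999843415,
     0.0012694250000322427
    ],
    "vectorized": [
     0.00044841199996881187,
     0.00039307800000187854
    ]
   }
  },
  {
   "signature": [
    100.0,
    100.0,
    9.0
   ],
   "times": {
    "unthreaded": [
     0.0012583929999436805,
     0.001210517999993499
    ],
    "threaded": [
     0.0025939370000287454,
     0.0025670800000625604
    ],
    "vectorized": [
     0.0012347539999382207,
     0.0009880250000833257
    ]
   }
  },
  {
   "signature": [
    100.0,
    100.0,
    13.0
   ],
   "times": {
    "unthreaded": [
     0.0024200369999789473,
     0.0023093930000186447
    ],
    "threaded": [
     0.005098115999999209,
     0.004966369000044324
    ],
    "vectorized": [
     0.0020681929999000204,
     0.0021187380000355915
    ]
   }
  },
  {
   "signature": [
    100.0,
    100.0,
    17.0
   ],
   "times": {
    "unthreaded": [
     0.003989195000031032,
     0.0038552239999489757
    ],
    "threaded": [
     0.0076958489999015,
     0.0076146929999367785
    ],
    "vectorized": [
     0.0033575009999822214,
     0.003338534000022264
    ]
   }
  },
  {
   "signature": [
    100.0,
    100.0,
    21.0
   ],
   "times": {
    "unthreaded": [
     0.005730341999992561,
     0.005712752000022192
    ],
    "threaded": [
     0.01107093200005238,
     0.01108695200002785
    ],
    "vectorized": [
     0.005613642999946933,
     0.005255259000023216
    ]
   }
  },
  {
   "signature": [
    500.0,
    500.0,
    1.0
   ],
   "times": {
    "unthreaded": [
     0.002594950999991852,
     0.003355673999976716
    ],
    "threaded": [
     0.0065472620000264214,
     0.00596030500003053
    ],
    "vectorized": [
     0.003982251000024917,
     0.003866534999929172
    ]
   }
  },
  {
   "signature": [
    500.0,
    500.0,
    5.0
   ],
   "times": {
    "unthreaded": [
     0.011540697999976146,
     0.010755141000004187
    ],
    "threaded": [
     0.02130433299998913,
     0.0218453900000668
    ],
    "vectorized": [
     0.014641399999959503,
     0.014186286999915865
    ]
   }
  },
  {
   "signature": [
    500.0,
    500.0,
    9.0
   ],
   "times": {
    "unthreaded": [
     0.030760458000031576,
     0.029547091000040382
    ],
    "threaded": [
     0.055040194999946834,
     0.053070094999952744
    ],
    "vectorized": [
     0.03806087700002081,
     0.038077442000030715
    ]
   }
  },
  {
   "signature": [
    500.0,
    500.0,
    13.0
   ],
   "times": {
    "unthreaded": [
     0.05776261300002261,
     0.057770976000028895
    ],
    "threaded": [
     0.12080605699998159,
     0.08962456300002941
    ],
    "vectorized": [
     0.07082653399993433,
     0.08262091699998564
    ]
   }
  },
  {
   "signature": [
    500.0,
    500.0,
    17.0
   ],
   "times": {
    "unthreaded": [
     0.09825465899996288,
     0.10074520499995288
    ],
    "threaded": [
     0.12200852500006931,
     0.10639296500005457
    ],
    "vectorized": [
     0.11182973299992227,
     0.10766799400005311
    ]
   }
  },
  {
   "signature": [
    500.0,
    500.0,
    21.0
   ],
   "times": {
    "unthreaded": [
     0.12198611400003756,
     0.12169012399999701
    ],
    "threaded": [
     0.21375155999999151,
     0.2200523559999965
    ],
    "vectorized": [
     0.19334588000003805,
     0.18386930400004076
    ]
   }
  },
  {
   "signature": [
    1000.0,
    1000.0,
    1.0
   ],
   "times": {
    "unthreaded": [
     0.007256569000105628,
     0.005524424000100225
    ],
    "threaded": [
     0.05322977499997705,
     0.02085070399994038
    ],
    "vectorized": [
     0.06399540600000364,
     0.016436410000096657
    ]
   }
  },
  {
   "signature": [
    1000.0,
    1000.0,
    5.0
   ],
   "times": {
    "unthreaded": [
     0.036472501000048396,
     0.029075945000045067
    ],
    "threaded": [
     0.06292663700003231,
     0.06508468599997741
    ],
    "vectorized": [
     0.07622976199991172,
     0.05158398200001102
    ]
   }
  },
  {
   "signature": [
    1000.0,
    1000.0,
    9.0
   ],
   "times": {
    "unthreaded": [
     0.07958021000001736,
     0.085776831999965
    ],
    "threaded": [
     0.1551984860000175,
     4.911234197999988
    ],
    "vectorized": [
     0.13742131499998322,
     0.1301848409999593
    ]
   }
  },
  {
   "signature": [
    1000.0,
    1000.0,
    13.0
   ],
   "times": {
    "unthreaded": [
     0.2542649629999687,
     0.17567794400008552
    ],
    "threaded": [
     0.33122609899999134,
     0.31422737200000483
    ],
    "vectorized": [
     0.2810485030000791,
     0.2742215519999718
    ]
   }
  },
  {
   "signature": [
    1000.0,
    1000.0,
    17.0
   ],
   "times": {
    "unthreaded": [
     0.2688168529999757,
     0.2466752010000164
    ],
    "threaded": [
     0.46952786099996047,
     0.6219547629999624
    ],
    "vectorized": [
     0.49277321799991114,
     0.49011580599994886
    ]
   }
  },
  {
   "signature": [
    1000.0,
    1000.0,
    21.0
   ],
   "times": {
    "unthreaded": [
     0.6270857229999365,
     0.6036278379999658
    ],
    "threaded": [
     1.137654012999974,
     1.1444583239999702
    ],
    "vectorized": [
     0.6563144899999998,
     0.6732076790000292
    ]
   }
  }
 ]
}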