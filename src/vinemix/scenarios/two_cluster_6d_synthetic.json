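{
 "name": "two_cluster_6d_synthetic",
 "n_per_cluster": [
  300,
  300
 ],
 "clusters": [
  {
   "margins": [
    {
     "family": "normal",
     "parameters": [
      1.0,
      0.4
     ],
     "parameterization": "rate"
    },
    {
     "family": "normal",
     "parameters": [
      10.0,
      4.0
     ],
     "parameterization": "rate"
    },
    {
     "family": "normal",
     "parameters": [
      1.2,
      0.2
     ],
     "parameterization": "rate"
    },
    {
     "family": "gamma",
     "parameters": [
      0.9,
      0.9
     ],
     "parameterization": "rate"
    },
    {
     "family": "normal",
     "parameters": [
      1.2,
      0.45
     ],
     "parameterization": "rate"
    },
    {
     "family": "normal",
     "parameters": [
      0.8,
      0.8
     ],
     "parameterization": "rate"
    }
   ],
   "vine": {
    "n": 6,
    "truncation_level": 2,
    "order": [
     1,
     2,
     3,
     4,
     5,
     6
    ],
    "structure_matrix": [
     [
      1,
      0,
      0,
      0,
      0,
      0
     ],
     [
      6,
      2,
      0,
      0,
      0,
      0
     ],
     [
      5,
      6,
      3,
      0,
      0,
      0
     ],
     [
      4,
      5,
      6,
      4,
      0,
      0
     ],
     [
      3,
      4,
      5,
      6,
      5,
      0
     ],
     [
      2,
      3,
      4,
      5,
      6,
      6
     ]
    ],
    "trees": [
     [
      {
       "conditioned": [
        1,
        2
       ],
       "conditioning": [],
       "family": "gumbel",
       "rotation": 0,
       "parameters": [
        2.0
       ]
      },
      {
       "conditioned": [
        2,
        3
       ],
       "conditioning": [],
       "family": "gaussian",
       "rotation": 0,
       "parameters": [
        0.6
       ]
      },
      {
       "conditioned": [
        3,
        4
       ],
       "conditioning": [],
       "family": "clayton",
       "rotation": 0,
       "parameters": [
        2.0
       ]
      },
      {
       "conditioned": [
        4,
        5
       ],
       "conditioning": [],
       "family": "frank",
       "rotation": 0,
       "parameters": [
        6.0
       ]
      },
      {
       "conditioned": [
        5,
        6
       ],
       "conditioning": [],
       "family": "joe",
       "rotation": 0,
       "parameters": [
        2.5
       ]
      }
     ],
     [
      {
       "conditioned": [
        1,
        3
       ],
       "conditioning": [
        2
       ],
       "family": "gaussian",
       "rotation": 0,
       "parameters": [
        0.4
       ]
      },
      {
       "conditioned": [
        2,
        4
       ],
       "conditioning": [
        3
       ],
       "family": "clayton",
       "rotation": 180,
       "parameters": [
        1.0
       ]
      },
      {
       "conditioned": [
        3,
        5
       ],
       "conditioning": [
        4
       ],
       "family": "independence",
       "rotation": 0,
       "parameters": []
      },
      {
       "conditioned": [
        4,
        6
       ],
       "conditioning": [
        5
       ],
       "family": "frank",
       "rotation": 0,
       "parameters": [
        3.0
       ]
      }
     ]
    ]
   }
  },
  {
   "margins": [
    {
     "family": "normal",
     "parameters": [
      1.5,
      0.2
     ],
     "parameterization": "rate"
    },
    {
     "family": "gamma",
     "parameters": [
      1.5,
      0.5
     ],
     "parameterization": "rate"
    },
    {
     "family": "normal",
     "parameters": [
      1.0,
      0.3
     ],
     "parameterization": "rate"
    },
    {
     "family": "gamma",
     "parameters": [
      1.5,
      0.25
     ],
     "parameterization": "rate"
    },
    {
     "family": "normal",
     "parameters": [
      1.3,
      0.3
     ],
     "parameterization": "rate"
    },
    {
     "family": "lognormal",
     "parameters": [
      1.2,
      0.25
     ],
     "parameterization": "rate"
    }
   ],
   "vine": {
    "n": 6,
    "truncation_level": 2,
    "order": [
     5,
     4,
     3,
     2,
     1,
     6
    ],
    "structure_matrix": [
     [
      5,
      0,
      0,
      0,
      0,
      0
     ],
     [
      6,
      4,
      0,
      0,
      0,
      0
     ],
     [
      4,
      6,
      3,
      0,
      0,
      0
     ],
     [
      3,
      3,
      6,
      2,
      0,
      0
     ],
     [
      2,
      2,
      2,
      6,
      1,
      0
     ],
     [
      1,
      1,
      1,
      1,
      6,
      6
     ]
    ],
    "trees": [
     [
      {
       "conditioned": [
        1,
        2
       ],
       "conditioning": [],
       "family": "gaussian",
       "rotation": 0,
       "parameters": [
        0.7
       ]
      },
      {
       "conditioned": [
        1,
        3
       ],
       "conditioning": [],
       "family": "gumbel",
       "rotation": 0,
       "parameters": [
        2.5
       ]
      },
      {
       "conditioned": [
        1,
        4
       ],
       "conditioning": [],
       "family": "frank",
       "rotation": 0,
       "parameters": [
        -5.0
       ]
      },
      {
       "conditioned": [
        1,
        5
       ],
       "conditioning": [],
       "family": "clayton",
       "rotation": 0,
       "parameters": [
        1.5
       ]
      },
      {
       "conditioned": [
        1,
        6
       ],
       "conditioning": [],
       "family": "student_t",
       "rotation": 0,
       "parameters": [
        0.5,
        5.0
       ]
      }
     ],
     [
      {
       "conditioned": [
        2,
        3
       ],
       "conditioning": [
        1
       ],
       "family": "clayton",
       "rotation": 90,
       "parameters": [
        1.5
       ]
      },
      {
       "conditioned": [
        2,
        4
       ],
       "conditioning": [
        1
       ],
       "family": "gaussian",
       "rotation": 0,
       "parameters": [
        0.35
       ]
      },
      {
       "conditioned": [
        2,
        5
       ],
       "conditioning": [
        1
       ],
       "family": "independence",
       "rotation": 0,
       "parameters": []
      },
      {
       "conditioned": [
        2,
        6
       ],
       "conditioning": [
        1
       ],
       "family": "gumbel",
       "rotation": 0,
       "parameters": [
        1.6
       ]
      }
     ]
    ]
   }
  }
 ]
}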