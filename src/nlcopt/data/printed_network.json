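{
 "name": "published-nlc-surrogate",
 "layer_sizes": [
  4,
  9,
  9,
  4
 ],
 "activations": [
  "tanh_half",
  "tanh_half",
  "identity"
 ],
 "input_space": "actual",
 "input_names": [
  "X1",
  "X2",
  "X3",
  "X4"
 ],
 "response_names": [
  "Y1",
  "Y2",
  "Y3",
  "Y4"
 ],
 "weights": [
  [
   [
    0.69,
    -0.09,
    -0.28,
    -2.79
   ],
   [
    -0.66,
    -0.26,
    -1.99,
    -0.62
   ],
   [
    -0.24,
    0.07,
    -0.07,
    -2.57
   ],
   [
    0.22,
    0.26,
    -0.29,
    -1.0
   ],
   [
    0.05,
    -0.22,
    0.74,
    2.24
   ],
   [
    0.09,
    0.05,
    -1.88,
    4.23
   ],
   [
    0.05,
    -0.14,
    -1.91,
    2.81
   ],
   [
    -1.22,
    0.13,
    0.66,
    0.01
   ],
   [
    -0.92,
    -0.08,
    -1.42,
    -2.4
   ]
  ],
  [
   [
    -2.47,
    1.8,
    -1.04,
    0.17,
    2.64,
    2.81,
    2.45,
    0.76,
    -4.03
   ],
   [
    -0.58,
    3.96,
    -0.95,
    1.12,
    -2.31,
    -2.05,
    1.0,
    -1.42,
    0.14
   ],
   [
    -0.55,
    2.3,
    0.51,
    0.31,
    -1.62,
    0.14,
    0.49,
    -0.77,
    4.15
   ],
   [
    0.81,
    -0.25,
    0.48,
    -5.18,
    0.6,
    -0.7,
    -0.78,
    1.88,
    2.67
   ],
   [
    2.41,
    -1.86,
    -1.43,
    1.12,
    -1.49,
    -0.55,
    3.74,
    -1.08,
    -0.14
   ],
   [
    0.12,
    2.43,
    -1.94,
    -0.92,
    -1.63,
    -2.39,
    1.14,
    -1.9,
    0.5
   ],
   [
    -0.64,
    -0.17,
    -1.41,
    -0.68,
    0.32,
    -2.35,
    0.73,
    -1.95,
    -0.18
   ],
   [
    0.1,
    0.87,
    -1.34,
    -1.35,
    -0.56,
    -3.26,
    1.15,
    -0.77,
    -0.94
   ],
   [
    -1.09,
    -2.39,
    -2.54,
    -0.35,
    0.4,
    -1.37,
    -0.1,
    0.05,
    1.26
   ]
  ],
  [
   [
    18.19,
    -40.03,
    26.22,
    -146.97,
    -78.91,
    180.0,
    121.12,
    -112.0,
    -102.29
   ],
   [
    -0.02,
    0.09,
    -0.04,
    -0.07,
    -0.1,
    0.2,
    0.03,
    -0.13,
    0.13
   ],
   [
    -2.54,
    0.15,
    -1.86,
    0.35,
    0.94,
    2.5,
    -0.33,
    -0.1,
    3.16
   ],
   [
    3.9,
    29.57,
    -10.98,
    -1.71,
    -5.88,
    -18.64,
    -12.3,
    14.02,
    11.59
   ]
  ]
 ],
 "biases": [
  [
   3.07,
   18.45,
   0.5,
   -4.35,
   1.08,
   -2.99,
   7.28,
   2.31,
   14.92
  ],
  [
   1.97,
   -0.61,
   -1.34,
   0.34,
   2.29,
   -0.97,
   -0.92,
   -0.82,
   -1.94
  ],
  [
   170.31,
   0.3,
   -10.73,
   61.43
  ]
 ],
 "provenance": "Coefficients of the published 4-9-9-4 TanH(0.5z) surrogate for NLC responses; inputs in actual units (X1 wt%, X2 % of total lipid, X3 wt%, X4 wt%).",
 "sha256": "9bcb7305dc77fd749c9699d78ba08ecccc3cdbb9c5df70b1bc926ff25f0f8337"
}
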