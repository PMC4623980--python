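{
  "stock": "WEST",
  "comment": "Published biometric relationships for the West Atlantic stock. Same conventions as the East fixture. The DWT<->RWT ranges are stored exactly as printed even though the X/Y ranges appear interchanged relative to the physical ordering of the two weight types.",
  "linear": [
    {"x": "CFL", "y": "SFL", "alpha": 1.8575, "beta": 0.9606, "r2": 0.991, "residual_se": 2.565, "n": 1035, "x_range": [55, 274], "y_range": [53, 265], "months": "3,6-10", "method": "A"},
    {"x": "SFL", "y": "CFL", "alpha": -0.8319, "beta": 1.0314, "r2": 0.991, "residual_se": 2.670, "n": 1035, "x_range": [53, 265], "y_range": [55, 274], "months": "3,6-10", "method": "A"},
    {"x": "DWT", "y": "RWT", "alpha": 6.1971, "beta": 1.2303, "r2": 0.976, "residual_se": 12.581, "n": 1960, "x_range": [93, 637], "y_range": [70, 514], "months": "7-10", "method": "A"},
    {"x": "RWT", "y": "DWT", "alpha": 0.2911, "beta": 0.7967, "r2": 0.976, "residual_se": 10.135, "n": 1960, "x_range": [70, 514], "y_range": [93, 637], "months": "7-10", "method": "A"}
  ],
  "power": [
    {"x": "SFL", "y": "RWT", "alpha": 1.77e-05, "beta": 3.0013, "residual_se": 30.651, "n": 51204, "x_range": [53, 353], "y_range": [4, 637], "months": "1-12", "method": "B", "standardized": true},
    {"x": "CFL", "y": "RWT", "alpha": 4.94e-05, "beta": 2.8094, "residual_se": 32.625, "n": 2977, "x_range": [56, 338], "y_range": [4, 637], "months": "3,6-10", "method": "C", "standardized": false},
    {"x": "CFL", "y": "DWT", "alpha": 8.31e-06, "beta": 3.0780, "residual_se": 24.750, "n": 49344, "x_range": [127, 366], "y_range": [25, 514], "months": "1-12", "method": "C", "standardized": false},
    {"x": "SFL", "y": "GGTWT", "alpha": 1.27e-05, "beta": 3.0491, "residual_se": 18.242, "n": 2324, "x_range": [92, 289], "y_range": [11, 403], "months": "1-3,9-12", "method": "C", "standardized": false}
  ]
}
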