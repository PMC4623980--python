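{
  "stock": "EAST",
  "comment": "Published biometric relationships for the East Atlantic + Mediterranean stock. Linear rows: Y = alpha + beta * X (method A = robust linear fit). Power rows: Y = alpha * X^beta (B = CV-weighted nonlinear, C = unweighted Gauss-Newton). Lengths cm, weights kg.",
  "linear": [
    {"x": "SFL", "y": "LD1", "alpha": 5.6891, "beta": 0.2543, "r2": 0.978, "residual_se": 2.052, "n": 636, "x_range": [56, 300], "y_range": [17, 71], "months": "2-8,10,11", "method": "A"},
    {"x": "SFL", "y": "CFL", "alpha": -1.887, "beta": 1.0507, "r2": 0.990, "residual_se": 4.121, "n": 222, "x_range": [78, 242], "y_range": [84, 252], "months": "6-7", "method": "A"},
    {"x": "LD1", "y": "SFL", "alpha": -19.733, "beta": 3.8648, "r2": 0.978, "residual_se": 8.063, "n": 636, "x_range": [17, 71], "y_range": [56, 300], "months": "2-8,10,11", "method": "A"},
    {"x": "LD1", "y": "CFL", "alpha": -27.832, "beta": 4.1273, "r2": 0.964, "residual_se": 8.839, "n": 312, "x_range": [24, 71], "y_range": [84, 283], "months": "5-7", "method": "A"},
    {"x": "CFL", "y": "LD1", "alpha": 7.9182, "beta": 0.2355, "r2": 0.964, "residual_se": 2.116, "n": 312, "x_range": [84, 283], "y_range": [24, 71], "months": "5-7", "method": "A"},
    {"x": "CFL", "y": "SFL", "alpha": 2.9457, "beta": 0.9442, "r2": 0.990, "residual_se": 3.886, "n": 222, "x_range": [84, 252], "y_range": [78, 242], "months": "6-7", "method": "A"},
    {"x": "CFL", "y": "HeadL", "alpha": 4.4041, "beta": 0.2242, "r2": 0.865, "residual_se": 3.048, "n": 306, "x_range": [84, 284], "y_range": [22, 74], "months": "5,7", "method": "A"},
    {"x": "CFL", "y": "PreopL", "alpha": 1.0934, "beta": 0.1892, "r2": 0.646, "residual_se": 3.100, "n": 294, "x_range": [153, 284], "y_range": [33, 74], "months": "5", "method": "A"},
    {"x": "HeadL", "y": "PreopL", "alpha": -2.2179, "beta": 0.8358, "r2": 0.783, "residual_se": 2.428, "n": 294, "x_range": [38, 74], "y_range": [33, 74], "months": "5", "method": "A"},
    {"x": "RWT", "y": "GWT", "alpha": -0.2169, "beta": 0.9540, "r2": 1.000, "residual_se": 1.090, "n": 236, "x_range": [0.3, 370], "y_range": [0.3, 358], "months": "5-11", "method": "A"},
    {"x": "RWT", "y": "GGWT", "alpha": 1.2985, "beta": 0.7421, "r2": 0.991, "residual_se": 5.918, "n": 187, "x_range": [3, 300], "y_range": [2.8, 239], "months": "5-8,10", "method": "A"},
    {"x": "GGWT", "y": "RWT", "alpha": -1.6151, "beta": 1.3373, "r2": 0.991, "residual_se": 7.812, "n": 187, "x_range": [2.8, 239], "y_range": [3, 300], "months": "5-8,10", "method": "A"},
    {"x": "GWT", "y": "RWT", "alpha": 0.2312, "beta": 1.0479, "r2": 1.000, "residual_se": 1.140, "n": 236, "x_range": [0.3, 358], "y_range": [0.3, 370], "months": "5-11", "method": "A"}
  ],
  "power": [
    {"x": "SFL", "y": "RWT", "alpha": 3.51e-05, "beta": 2.8785, "residual_se": 15.965, "n": 74272, "x_range": [27, 300], "y_range": [0.25, 513], "months": "1-12", "method": "B", "standardized": true},
    {"x": "SFL", "y": "GGTWT", "alpha": 4.59e-05, "beta": 2.8077, "residual_se": 13.407, "n": 8034, "x_range": [75, 281], "y_range": [8, 362], "months": "1,8-12", "method": "C", "standardized": false},
    {"x": "SFL", "y": "GGWT", "alpha": 1.07e-04, "beta": 2.6301, "residual_se": 14.249, "n": 3469, "x_range": [55, 289], "y_range": [2.8, 385], "months": "1-12", "method": "C", "standardized": false},
    {"x": "CFL", "y": "GGWT", "alpha": 2.55e-05, "beta": 2.8938, "residual_se": 15.357, "n": 4962, "x_range": [94, 289], "y_range": [10, 338], "months": "4-8", "method": "C", "standardized": false},
    {"x": "LD1", "y": "GGWT", "alpha": 3.85e-03, "beta": 2.6211, "residual_se": 21.820, "n": 2044, "x_range": [29, 76], "y_range": [20, 350], "months": "5-7,9", "method": "C", "standardized": false},
    {"x": "LD1", "y": "RWT", "alpha": 1.12e-03, "beta": 2.9180, "residual_se": 20.019, "n": 2796, "x_range": [17, 79], "y_range": [3, 425], "months": "2-8,10-11", "method": "C", "standardized": false}
  ]
}
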