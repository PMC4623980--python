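{
  "comment": "Published monthly weight-length coefficients: RWT_std = alpha * SFL_std^beta_m, SFL in cm, RWT in kg, months January..December. The monthly alpha differs in the fourth digit from the annual CV-weighted alpha; both are stored verbatim.",
  "EAST": {
    "alpha": 3.508e-05,
    "beta_by_month": [2.87767028, 2.87585971, 2.87549667, 2.87961024,
                      2.88691388, 2.88309179, 2.87153307, 2.87200195,
                      2.87577309, 2.87633165, 2.87716283, 2.87529487]
  },
  "WEST": {
    "alpha": 1.771e-05,
    "beta_by_month": [2.99789075, 3.00292688, 3.00833823, 3.01618530,
                      2.99883106, 2.98858373, 2.99247363, 2.99823761,
                      3.00172394, 3.00774859, 3.00493806, 2.99596985]
  }
}
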