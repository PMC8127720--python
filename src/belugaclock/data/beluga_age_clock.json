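{
  "name": "beluga_age_clock",
  "trait": "age_linear",
  "intercept": 77.9708623,
  "coefficients": {
    "cg00952468": -4.525104457,
    "cg02534193": -9.85801758,
    "cg02714609": -14.10074358,
    "cg07279255": 14.33543764,
    "cg07493173": -0.175897809,
    "cg09622321": -8.372865623,
    "cg12584622": -6.025047791,
    "cg14043264": -5.78974944,
    "cg14671961": -5.341584389,
    "cg15809488": -0.469547261,
    "cg15992086": -0.379907718,
    "cg16678811": -2.632026911,
    "cg17856858": -1.525713524,
    "cg18629679": -2.129559849,
    "cg21419180": 30.73879442,
    "cg21420547": 5.593128066,
    "cg22069272": -5.967431136,
    "cg22416332": -9.317426596,
    "cg25579908": -19.26589983,
    "cg26286303": -0.357946396,
    "cg26313355": -1.762140707,
    "cg26899365": -0.44830474,
    "cg27600712": -0.104727313
  },
  "error_medae": 2.87,
  "error_mae": 3.65,
  "provenance": {
    "species": "Delphinapterus leucas",
    "tissue": "skin",
    "platform": "HorvathMammalMethylChip40 (GPL28271)",
    "training": "67 Cook Inlet calibration samples, tooth growth-layer-group ages, elastic net alpha=0.9 at lambda.min",
    "note": "published clock coefficients transcribed digit-for-digit"
  }
}
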