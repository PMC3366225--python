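{
  "internal_411": {
    "description": "10-fold cross-validation classification of 411 CHD in-patients",
    "qi deficiency": {
      "TN": 144,
      "FP": 42,
      "FN": 67,
      "TP": 158,
      "printed": {
        "sensitivity": 70.2,
        "specificity": 77.4,
        "accuracy": 73.5,
        "correct": 302
      }
    },
    "phlegm-blood stasis": {
      "TN": 278,
      "FP": 64,
      "FN": 19,
      "TP": 50,
      "printed": {
        "sensitivity": 72.5,
        "specificity": 81.3,
        "accuracy": 79.8,
        "correct": 328
      }
    }
  },
  "external_212": {
    "description": "10-fold cross-validation classification of the 212-patient external-validation subset",
    "qi deficiency": {
      "TN": 85,
      "FP": 31,
      "FN": 29,
      "TP": 67,
      "printed": {
        "sensitivity": 69.8,
        "specificity": 73.3,
        "accuracy": 71.7,
        "correct": 152
      }
    },
    "phlegm-blood stasis": {
      "TN": 132,
      "FP": 42,
      "FN": 5,
      "TP": 33,
      "printed": {
        "sensitivity": 86.8,
        "specificity": 75.9,
        "accuracy": 77.8,
        "correct": 165
      }
    }
  }
}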