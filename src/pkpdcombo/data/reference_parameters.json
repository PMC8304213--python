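{
  "comment": "Published two-compartment PK estimates (with reported CV%, AUC, Cmax), four-parameter Hill dose-response constants for the A549 lung-carcinoma combination assays, Bottom-modulation quadratics and the clinical dose regimens used throughout the analyses.",
  "molecular_weights": {
    "itraconazole": 705.64
  },
  "pk": {
    "gemcitabine": {
      "vd1": 68019.62, "vd2": 444.79, "cl": 3771.20, "k12": 6.64e-4, "k21": 0.102,
      "cv_percent": {"vd1": 148.8, "vd2": 19137.5, "cl": 10.3, "k12": 45998.6, "k21": 29203.6},
      "reported": {"k10": 0.0554, "vss": 68464.40, "auc": 499.58, "cmax": 4.16}
    },
    "fluorouracil": {
      "vd1": 9265.14, "vd2": 2791.84, "cl": 850.01, "k12": 3.21e-2, "k21": 0.107,
      "cv_percent": {"vd1": 5.1, "vd2": 14.2, "cl": 1.6, "k12": 29.5, "k21": 28.1},
      "reported": {"k10": 0.0917, "vss": 12056.99, "auc": 1058.81, "cmax": 97.14}
    },
    "itraconazole": {
      "vd1": 8145.37, "vd2": 82776.88, "cl": 228.45, "k12": 2.38e-2, "k21": 2.34e-3,
      "cv_percent": {"vd1": 2.6, "vd2": 22.9, "cl": 7.9, "k12": 9.4, "k21": 15.3},
      "reported": {"k10": 0.0280, "vss": 90922.24, "auc": 437.73, "cmax": 3.88}
    }
  },
  "hill": {
    "gem_I6": {"bottom": 34.33, "top": 80.39, "steepness": 4.30, "ec50": 0.0016,
               "se": {"bottom": 2.43, "top": 1.71, "steepness": 1.30, "ec50": 3.2e-7}},
    "gem_I4": {"bottom": 12.83, "top": 73.07, "steepness": 4.37, "ec50": 0.0018,
               "se": {"bottom": 2.79, "top": 1.97, "steepness": 0.99, "ec50": 3.1e-7}},
    "gem_I2": {"bottom": -5.51, "top": 67.47, "steepness": 5.35, "ec50": 0.0022,
               "se": {"bottom": 1.83, "top": 1.29, "steepness": 1.12, "ec50": 1.6e-7}},
    "gem_I0": {"bottom": -1.06, "top": 70.12, "steepness": 23.14, "ec50": 0.0026,
               "se": {"bottom": 2.35, "top": 1.67, "steepness": 4.20e5, "ec50": 2.2e5}},
    "fu_I6":  {"bottom": 33.22, "top": 63.24, "steepness": 2.77, "ec50": 0.36,
               "se": {"bottom": 1.58, "top": 1.62, "steepness": 1.23, "ec50": 0.01}},
    "fu_I4":  {"bottom": 13.42, "top": 56.05, "steepness": 2.90, "ec50": 0.20,
               "se": {"bottom": 3.09, "top": 2.87, "steepness": 2.40, "ec50": 0.0071}},
    "fu_I2":  {"bottom": -6.99, "top": 57.52, "steepness": 1.70, "ec50": 0.27,
               "se": {"bottom": 2.14, "top": 2.11, "steepness": 0.26, "ec50": 0.002}},
    "fu_I0":  {"bottom": -0.47, "top": 57.80, "steepness": 2.19, "ec50": 0.28,
               "se": {"bottom": 1.32, "top": 1.32, "steepness": 0.27, "ec50": 0.001}}
  },
  "hill_average": {
    "gem_combo_avg": {"top": 72.76, "steepness": 4.67, "ec50": 0.0021},
    "fu_combo_avg": {"top": 58.65, "steepness": 2.39, "ec50": 0.28}
  },
  "averaging_exclusions": {
    "gem": [["gem_I2", "bottom"], ["gem_I0", "steepness"]],
    "fu": [["fu_I2", "bottom"]]
  },
  "bottom_modulation": {
    "gem": {"a": 2.44, "b": -1.95, "c": -1.06},
    "fu": {"a": 2.15, "b": -1.15, "c": -0.47}
  },
  "collapse": {
    "gem": {"ec50": 0.0019, "steepness": 4.67, "threshold": 0.008},
    "fu": {"ec50": 0.28, "steepness": 2.62, "threshold": 0.5}
  },
  "regimens": {
    "gemcitabine_regimen": {"route": "infusion", "rate": 15.7, "duration": 120.0},
    "fluorouracil_regimen": {"route": "bolus", "dose": 900.0},
    "itraconazole_regimen_100": {"route": "infusion", "dose": 100.0, "duration": 60.0},
    "itraconazole_regimen_300": {"route": "infusion", "dose": 300.0, "duration": 60.0},
    "itraconazole_regimen_500": {"route": "infusion", "dose": 500.0, "duration": 60.0}
  },
  "rounded_infusion_rates": {
    "itraconazole_regimen_100": 1.7,
    "itraconazole_regimen_300": 5.0,
    "itraconazole_regimen_500": 8.3
  }
}
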