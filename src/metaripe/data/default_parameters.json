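[
  {"cultivar": "Miracle", "temperature_C": 12, "alpha": 639.9, "beta": -0.120, "gamma": -608.8},
  {"cultivar": "Miracle", "temperature_C": 15, "alpha": 485.6, "beta": -0.217, "gamma": -455.4},
  {"cultivar": "Miracle", "temperature_C": 20, "alpha": 342.3, "beta": -0.346, "gamma": -311.9},
  {"cultivar": "Miracle", "temperature_C": 25, "alpha": 237.6, "beta": -0.454, "gamma": -208.9},
  {"cultivar": "Miracle", "temperature_C": 30, "alpha": 363.9, "beta": -0.580, "gamma": -334.6},
  {"cultivar": "Rei-getsu", "temperature_C": 12, "alpha": 292.6, "beta": -0.083, "gamma": -256.6},
  {"cultivar": "Rei-getsu", "temperature_C": 15, "alpha": 451.8, "beta": -0.189, "gamma": -419.5},
  {"cultivar": "Rei-getsu", "temperature_C": 20, "alpha": 270.1, "beta": -0.301, "gamma": -237.7},
  {"cultivar": "Rei-getsu", "temperature_C": 25, "alpha": 294.8, "beta": -0.486, "gamma": -267.7},
  {"cultivar": "Rei-getsu", "temperature_C": 30, "alpha": 531.8, "beta": -0.627, "gamma": -506.8},
  {"cultivar": "Momotaro York", "temperature_C": 12, "alpha": 876.4, "beta": -0.111, "gamma": -836.8},
  {"cultivar": "Momotaro York", "temperature_C": 15, "alpha": 776.4, "beta": -0.229, "gamma": -744.4},
  {"cultivar": "Momotaro York", "temperature_C": 20, "alpha": 1159.5, "beta": -0.299, "gamma": -1127.9},
  {"cultivar": "Momotaro York", "temperature_C": 25, "alpha": 4671.1, "beta": -0.614, "gamma": -4645.22},
  {"cultivar": "Momotaro York", "temperature_C": 30, "alpha": 186.7, "beta": -0.193, "gamma": -161.8}
]
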