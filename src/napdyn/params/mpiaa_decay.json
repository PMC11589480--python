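{
  "description": "MpIAA-mScarlet-I degradation kinetics measured by auxin-induced fluorescence decay time-lapse in gemmae (one-component exponential model).",
  "k_per_min": 0.10663802777845313,
  "half_life_min": 6.5,
  "provenance": {
    "half_life_min": "measured: in vivo MpIAA half-life after 3 uM 1-NAA treatment",
    "k_per_min": "derived: ln(2) / half_life_min"
  }
}
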