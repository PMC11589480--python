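{
  "description": "Default parameters of the minimal nuclear auxin pathway model. Only the IAA turnover rate is anchored to a measurement; all other values are order-of-magnitude defaults and should be treated as free.",
  "pi_I": 0.0067,
  "delta_I0": 0.0067,
  "delta_Imax": 0.09993802777845312,
  "K_aux": 1.0,
  "K_AI": 0.1,
  "K_1": 1.0,
  "K_2": 1.0,
  "lambda_m": 1.0,
  "delta_m": 0.05,
  "basal_m": 0.04,
  "s1": 2.0,
  "s2": 600.0,
  "n_sites": 1,
  "h": 1.0,
  "provenance": {
    "pi_I": "free: IAA production (conc/min) set so steady-state IAA = 1 a.u. without auxin",
    "delta_I0": "free: basal IAA decay 1/min (~103 min basal half-life)",
    "delta_Imax": "calibrated: delta_I0 + delta_Imax = ln(2)/6.5 so the saturating-auxin IAA half-life equals the measured 6.5 min",
    "K_aux": "free: auxin half-saturation of the TIR1 co-receptor (a.u.)",
    "K_AI": "free: ARF1-IAA dissociation constant (a.u.), tight enough that IAA sequesters ARF1 when abundant",
    "K_1": "free: ARF1-DNA dissociation constant (a.u.)",
    "K_2": "free: ARF2-DNA dissociation constant (a.u.)",
    "lambda_m": "free: maximal transcription rate (a.u./min)",
    "delta_m": "free: mRNA decay 1/min (~14 min mRNA half-life)",
    "basal_m": "free: basal ARF-independent transcription (a.u./min)",
    "s1": "free: scale from ARF1 fold change to nuclear concentration (a.u.)",
    "s2": "free: scale from ARF2 fold change to nuclear concentration (a.u.); large relative to s1/K_1 to reflect ARF2 excess over ARF1 in dormant apical-notch nuclei",
    "n_sites": "free: promoter auxin-response-element count",
    "h": "free: activation cooperativity exponent on per-site activator occupancy"
  }
}
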