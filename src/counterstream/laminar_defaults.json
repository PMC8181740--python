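{
  "_comment": "Default parameters of the bilaminar Wilson-Cowan rate model. Values marked 'inherited' follow the published reference implementation of the laminar cortical model (Mejias et al. 2016, public ModelDB code); the remainder are this package's defaults, documented in docs/methods.md. Units: time constants and durations in ms, conduction velocity in mm/ms.",
  "tau_ms": {"_comment": "inherited; [supraE, supraI, infraE, infraI]", "value": [6.0, 15.0, 30.0, 75.0]},
  "j_local": {
    "_comment": "inherited; 4x4 coupling, row = target population, column = source, order [supraE, supraI, infraE, infraI]; includes the interlaminar supraE->infraE (1.0) and infraE->supraI (0.75) pathways",
    "value": [
      [1.5, -3.25, 0.0, 0.0],
      [3.5, -2.5, 0.75, 0.0],
      [1.0, 0.0, 1.5, -3.25],
      [0.0, 0.0, 3.5, -2.5]
    ]
  },
  "background_drive": {"_comment": "constant external input per population; sets the operating point so the laminar resonances sit mid-band (supra ~47 Hz, infra ~10 Hz)", "value": [16.0, 6.0, 14.0, 6.0]},
  "noise_sigma": {"_comment": "additive noise amplitude per population", "value": [0.3, 0.3, 0.45, 0.45]},
  "interareal_gain": {"_comment": "global scaling G of inter-areal coupling", "value": 1.0},
  "fln_exponent": {"_comment": "inherited; g(FLN) = G * FLN^eta compresses the FLN range", "value": 0.3},
  "ff_targets": {"_comment": "feedforward (SLN-weighted, supragranular-E source) input coefficients per target population", "value": [1.0, 0.0, 0.0, 0.0]},
  "fb_targets": {"_comment": "feedback ((1-SLN)-weighted, infragranular-E source) input coefficients per target population", "value": [0.1, 0.5, 0.9, 0.5]},
  "conduction_velocity_mm_ms": {"_comment": "distance/velocity sets the inter-areal delay", "value": 3.5},
  "dt_ms": {"value": 0.2},
  "duration_ms": {"value": 11000.0},
  "transient_ms": {"value": 1000.0},
  "stability_bound": {"value": 1000000.0}
}
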