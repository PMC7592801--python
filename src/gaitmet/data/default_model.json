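{
  "version": "1.0",
  "description": "Default sagittal lower-limb model: eight EMG-driven Hill-type muscle-tendon units with generic parameters, constant literature-scale moment arms, and Hill/tendon curve constants. Generalized coordinates are hip extension, knee extension and ankle plantarflexion, all positive; a positive moment arm produces a positive moment.",
  "muscles": {
    "tibialis_anterior":       {"f_max": 1227, "l_opt": 0.07, "l_slack": 0.24, "pennation_opt": 0.20, "v_max": 10, "slow_twitch_ratio": 0.700, "width": 0.49},
    "soleus":                  {"f_max": 6195, "l_opt": 0.04, "l_slack": 0.28, "pennation_opt": 0.38, "v_max": 10, "slow_twitch_ratio": 0.803, "width": 0.80},
    "gastrocnemius_medialis":  {"f_max": 3116, "l_opt": 0.05, "l_slack": 0.40, "pennation_opt": 0.17, "v_max": 10, "slow_twitch_ratio": 0.566, "width": 0.61},
    "gastrocnemius_lateralis": {"f_max": 1575, "l_opt": 0.06, "l_slack": 0.38, "pennation_opt": 0.21, "v_max": 10, "slow_twitch_ratio": 0.507, "width": 0.61},
    "vastus_medialis":         {"f_max": 9594, "l_opt": 0.10, "l_slack": 0.20, "pennation_opt": 0.42, "v_max": 10, "slow_twitch_ratio": 0.503, "width": 0.76},
    "rectus_femoris":          {"f_max": 2192, "l_opt": 0.08, "l_slack": 0.45, "pennation_opt": 0.22, "v_max": 10, "slow_twitch_ratio": 0.387, "width": 0.76},
    "biceps_femoris":          {"f_max": 1870, "l_opt": 0.10, "l_slack": 0.33, "pennation_opt": 0.18, "v_max": 10, "slow_twitch_ratio": 0.542, "width": 0.78},
    "gluteus_maximus":         {"f_max": 3338, "l_opt": 0.15, "l_slack": 0.05, "pennation_opt": 0.35, "v_max": 10, "slow_twitch_ratio": 0.550, "width": 0.77}
  },
  "moment_arms": {
    "tibialis_anterior":       {"ankle": [-0.040]},
    "soleus":                  {"ankle": [0.050]},
    "gastrocnemius_medialis":  {"ankle": [0.050], "knee": [-0.022]},
    "gastrocnemius_lateralis": {"ankle": [0.045], "knee": [-0.016]},
    "vastus_medialis":         {"knee": [0.045]},
    "rectus_femoris":          {"knee": [0.045], "hip": [-0.040]},
    "biceps_femoris":          {"knee": [-0.035], "hip": [0.060]},
    "gluteus_maximus":         {"hip": [0.062]}
  },
  "reference_fiber_norm": {
    "tibialis_anterior": 1.00,
    "soleus": 1.12,
    "gastrocnemius_medialis": 1.15,
    "gastrocnemius_lateralis": 1.12,
    "vastus_medialis": 0.90,
    "rectus_femoris": 1.00,
    "biceps_femoris": 1.10,
    "gluteus_maximus": 1.00
  },
  "curves": {
    "fl_shape": 0.5,
    "af": 0.25,
    "ecc_plateau": 1.5,
    "ecc_curvature": 10.0,
    "fiber_damping": 0.1,
    "tendon_strain_iso": 0.045,
    "tendon_shape": 40.0,
    "pe_shape": 4.0,
    "pe_strain": 0.7
  }
}
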