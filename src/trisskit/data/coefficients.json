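{
  "schema_version": 1,
  "sets": [
    {
      "model_id": "adjusted_triss",
      "mechanism": "blunt",
      "intercept": -1.64790049,
      "slopes": [0.90535734, -0.07845091, -1.38013670],
      "covariate_order": ["rts", "iss", "age"],
      "provenance": "published two-center derivation cohort (Sao Paulo / San Diego, 2006-2010)"
    },
    {
      "model_id": "adjusted_triss",
      "mechanism": "penetrating",
      "intercept": -1.29803310,
      "slopes": [0.89538700, -0.09521947, -1.27540759],
      "covariate_order": ["rts", "iss", "age"],
      "provenance": "published two-center derivation cohort (Sao Paulo / San Diego, 2006-2010)"
    },
    {
      "model_id": "ntriss_like",
      "mechanism": "blunt",
      "intercept": -1.67602650,
      "slopes": [0.61944706, 0.89539814, -0.07289039, -1.33088941],
      "covariate_order": ["bmr", "sbp", "niss", "age"],
      "provenance": "published two-center derivation cohort (Sao Paulo / San Diego, 2006-2010)"
    },
    {
      "model_id": "ntriss_like",
      "mechanism": "penetrating",
      "intercept": -1.58632944,
      "slopes": [0.58883203, 0.96952677, -0.06659814, -1.00582810],
      "covariate_order": ["bmr", "sbp", "niss", "age"],
      "provenance": "published two-center derivation cohort (Sao Paulo / San Diego, 2006-2010)"
    },
    {
      "model_id": "triss_spo2",
      "mechanism": "blunt",
      "intercept": -2.97523446,
      "slopes": [0.75773826, 0.58321377, 0.38492625, -0.08441861, -1.59455370],
      "covariate_order": ["gcs", "sbp", "spo2", "iss", "age"],
      "provenance": "published two-center derivation cohort (Sao Paulo / San Diego, 2006-2010)"
    },
    {
      "model_id": "triss_spo2",
      "mechanism": "penetrating",
      "intercept": -3.5166820,
      "slopes": [0.8515884, 0.3453793, 1.3098071, -0.1955984, -4.0353761],
      "covariate_order": ["gcs", "sbp", "spo2", "iss", "age"],
      "provenance": "published two-center derivation cohort (Sao Paulo / San Diego, 2006-2010)"
    },
    {
      "model_id": "ntriss_like_spo2",
      "mechanism": "blunt",
      "intercept": -2.73634921,
      "slopes": [0.59396868, 0.66226833, 0.56405908, -0.06841853, -1.43274160],
      "covariate_order": ["bmr", "sbp", "spo2", "niss", "age"],
      "provenance": "published two-center derivation cohort (Sao Paulo / San Diego, 2006-2010)"
    },
    {
      "model_id": "ntriss_like_spo2",
      "mechanism": "penetrating",
      "intercept": -1.5156694,
      "slopes": [0.1832071, 1.0209288, 1.1288631, -0.1138697, -1.7286860],
      "covariate_order": ["bmr", "sbp", "spo2", "niss", "age"],
      "provenance": "published two-center derivation cohort (Sao Paulo / San Diego, 2006-2010)"
    },
    {
      "model_id": "triss_mtos_1987",
      "mechanism": "blunt",
      "intercept": -1.2470,
      "slopes": [0.9544, -0.0768, -1.9052],
      "covariate_order": ["rts", "iss", "age"],
      "provenance": "external literature: original MTOS coefficients (1987 revision); uses weighted RTS"
    },
    {
      "model_id": "triss_mtos_1987",
      "mechanism": "penetrating",
      "intercept": -0.6029,
      "slopes": [1.1430, -0.1516, -2.6676],
      "covariate_order": ["rts", "iss", "age"],
      "provenance": "external literature: original MTOS coefficients (1987 revision); uses weighted RTS"
    },
    {
      "model_id": "triss_mtos_1995",
      "mechanism": "blunt",
      "intercept": -0.4499,
      "slopes": [0.8085, -0.0835, -1.7430],
      "covariate_order": ["rts", "iss", "age"],
      "provenance": "external literature: re-estimated MTOS coefficients (1995 revision); uses weighted RTS"
    },
    {
      "model_id": "triss_mtos_1995",
      "mechanism": "penetrating",
      "intercept": -2.5355,
      "slopes": [0.9934, -0.0651, -1.1360],
      "covariate_order": ["rts", "iss", "age"],
      "provenance": "external literature: re-estimated MTOS coefficients (1995 revision); uses weighted RTS"
    }
  ]
}
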