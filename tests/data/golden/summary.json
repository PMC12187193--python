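{
  "class_counts": {
    "high": 1,
    "intermediate": 1,
    "low": 1
  },
  "class_percent": {
    "high": 33,
    "intermediate": 33,
    "low": 33
  },
  "config_hash": "4c73b77bc50bc4bf",
  "n_individuals": 3,
  "per_temperature_means": {
    "high": {
      "10.0": {
        "aerobic_scope": 5.553940469929595,
        "mmr": 6.225383577421008,
        "smr": 0.6714431074914128
      },
      "16.0": {
        "aerobic_scope": 6.400282688517179,
        "mmr": 7.418530485262836,
        "smr": 1.0182477967456562
      },
      "21.0": {
        "aerobic_scope": 5.3809154338219845,
        "mmr": 6.821361248907102,
        "smr": 1.4404458150851174
      }
    },
    "intermediate": {
      "10.0": {
        "aerobic_scope": 3.124565604867994,
        "mmr": 3.796005263980739,
        "smr": 0.6714396591127452
      },
      "16.0": {
        "aerobic_scope": 4.415630596360398,
        "mmr": 5.433879371262107,
        "smr": 1.0182487749017097
      },
      "21.0": {
        "aerobic_scope": 2.7145333114905004,
        "mmr": 4.154985493569379,
        "smr": 1.4404521820788785
      }
    },
    "low": {
      "10.0": {
        "aerobic_scope": 0.4872022237043028,
        "mmr": 1.158637978586711,
        "smr": 0.6714357548824081
      },
      "16.0": {
        "aerobic_scope": 2.8835837004433587,
        "mmr": 3.9018333782962222,
        "smr": 1.0182496778528636
      },
      "21.0": {
        "aerobic_scope": -0.04716425602808674,
        "mmr": 1.3932946812368552,
        "smr": 1.440458937264942
      }
    }
  },
  "pooled_stats": {
    "high": {
      "aerobic_scope": {
        "max": 6.400282688517179,
        "mean": 5.7783795307562515,
        "min": 5.3809154338219845,
        "sd": 0.5454879182940432
      },
      "mmr": {
        "max": 7.418530485262836,
        "mean": 6.821758437196983,
        "min": 6.225383577421008,
        "sd": 0.5965735530863164
      },
      "smr": {
        "max": 1.4404458150851174,
        "mean": 1.0433789064407286,
        "min": 0.6714431074914128,
        "sd": 0.3851168271803914
      }
    },
    "intermediate": {
      "aerobic_scope": {
        "max": 4.415630596360398,
        "mean": 3.4182431709062975,
        "min": 2.7145333114905004,
        "sd": 0.8877600338737776
      },
      "mmr": {
        "max": 5.433879371262107,
        "mean": 4.461623376270742,
        "min": 3.796005263980739,
        "sd": 0.8609169478854309
      },
      "smr": {
        "max": 1.4404521820788785,
        "mean": 1.0433802053644445,
        "min": 0.6714396591127452,
        "sd": 0.3851217427223655
      }
    },
    "low": {
      "aerobic_scope": {
        "max": 2.8835837004433587,
        "mean": 1.1078738893731914,
        "min": -0.04716425602808674,
        "sd": 1.5608478092093196
      },
      "mmr": {
        "max": 3.9018333782962222,
        "mean": 2.1512553460399295,
        "min": 1.158637978586711,
        "sd": 1.5205783528935282
      },
      "smr": {
        "max": 1.440458937264942,
        "mean": 1.0433814566667379,
        "min": 0.6714357548824081,
        "sd": 0.3851270809618587
      }
    }
  }
}
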