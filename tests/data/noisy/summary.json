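{
  "class_counts": {
    "high": 3,
    "intermediate": 3,
    "low": 3
  },
  "class_percent": {
    "high": 33,
    "intermediate": 33,
    "low": 33
  },
  "config_hash": "17e7af4b0ed66225",
  "n_individuals": 9,
  "per_temperature_means": {
    "high": {
      "10.0": {
        "aerobic_scope": 5.368591080588871,
        "mmr": 6.015695346597795,
        "smr": 0.6471042660089242
      },
      "16.0": {
        "aerobic_scope": 6.449776363988342,
        "mmr": 7.446056726050036,
        "smr": 0.9962803620616946
      },
      "21.0": {
        "aerobic_scope": 5.555926504350336,
        "mmr": 6.933357252289238,
        "smr": 1.377430747938903
      }
    },
    "intermediate": {
      "10.0": {
        "aerobic_scope": 2.8071918707595835,
        "mmr": 3.440378889905077,
        "smr": 0.6331870191454932
      },
      "16.0": {
        "aerobic_scope": 4.566583680945565,
        "mmr": 5.5350745829981465,
        "smr": 0.9684909020525817
      },
      "21.0": {
        "aerobic_scope": 3.2459746959773237,
        "mmr": 4.602404376283061,
        "smr": 1.3564296803057367
      }
    },
    "low": {
      "10.0": {
        "aerobic_scope": 0.5666610842122812,
        "mmr": 1.186057546850505,
        "smr": 0.6193964626382237
      },
      "16.0": {
        "aerobic_scope": 2.703162023145911,
        "mmr": 3.6921243295083204,
        "smr": 0.9889623063624097
      },
      "21.0": {
        "aerobic_scope": 0.3481883664382452,
        "mmr": 1.6414373048571116,
        "smr": 1.2932489384188663
      }
    }
  },
  "pooled_stats": {
    "high": {
      "aerobic_scope": {
        "max": 6.604645165395369,
        "mean": 5.791431316309183,
        "min": 5.191873793997373,
        "sd": 0.5296929949708459
      },
      "mmr": {
        "max": 7.614278678789361,
        "mean": 6.798369774979023,
        "min": 5.818908193607859,
        "sd": 0.649662109181163
      },
      "smr": {
        "max": 1.4347588074582507,
        "mean": 1.0069384586698404,
        "min": 0.6270343996104863,
        "sd": 0.31838043035830665
      }
    },
    "intermediate": {
      "aerobic_scope": {
        "max": 4.8237598558966654,
        "mean": 3.5399167492274906,
        "min": 2.709155789724608,
        "sd": 0.8203256868365849
      },
      "mmr": {
        "max": 5.7851650796895235,
        "mean": 4.525952616395429,
        "min": 3.351932809046256,
        "sd": 0.9337906258860008
      },
      "smr": {
        "max": 1.38957097657121,
        "mean": 0.9860358671679373,
        "min": 0.6023755757495222,
        "sd": 0.314141513251111
      }
    },
    "low": {
      "aerobic_scope": {
        "max": 2.793137339481205,
        "mean": 1.2060038245988123,
        "min": -0.08307404131717415,
        "sd": 1.1656246131019334
      },
      "mmr": {
        "max": 3.78746898770083,
        "mean": 2.173206393738645,
        "min": 0.7818323619511531,
        "sd": 1.194211427722931
      },
      "smr": {
        "max": 1.3518559928336216,
        "mean": 0.9672025691398333,
        "min": 0.6013810804500337,
        "sd": 0.2936033967779085
      }
    }
  }
}
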