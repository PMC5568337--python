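{
  "name": "paper_calibrated",
  "params": {
    "panel": {
      "variants": [
        {
          "rsid": "rs1052990",
          "risk_allele": "T",
          "locus_label": "CAV2",
          "risk_allele_frequency": 0.48342504840759015,
          "iop_effect_mmhg": 0.1694500755605397
        },
        {
          "rsid": "rs11656696",
          "risk_allele": "C",
          "locus_label": "GAS7",
          "risk_allele_frequency": 0.48342504840759015,
          "iop_effect_mmhg": 0.1694500755605397
        },
        {
          "rsid": "rs59072263",
          "risk_allele": "G",
          "locus_label": "GLCCI1/ICA1",
          "risk_allele_frequency": 0.48342504840759015,
          "iop_effect_mmhg": 0.1694500755605397
        },
        {
          "rsid": "rs2472493",
          "risk_allele": "C",
          "locus_label": "ABCA1",
          "risk_allele_frequency": 0.48342504840759015,
          "iop_effect_mmhg": 0.1694500755605397
        },
        {
          "rsid": "rs58073046",
          "risk_allele": "G",
          "locus_label": "ARHGEF12",
          "risk_allele_frequency": 0.48342504840759015,
          "iop_effect_mmhg": 0.1694500755605397
        },
        {
          "rsid": "rs2286885",
          "risk_allele": "T",
          "locus_label": "FAM125B",
          "risk_allele_frequency": 0.48342504840759015,
          "iop_effect_mmhg": 0.1694500755605397
        },
        {
          "rsid": "rs6445055",
          "risk_allele": "G",
          "locus_label": "FNDC3B",
          "risk_allele_frequency": 0.48342504840759015,
          "iop_effect_mmhg": 0.1694500755605397
        },
        {
          "rsid": "rs8176743",
          "risk_allele": "A",
          "locus_label": "ABO",
          "risk_allele_frequency": 0.48342504840759015,
          "iop_effect_mmhg": 0.1694500755605397
        },
        {
          "rsid": "rs747782",
          "risk_allele": "G",
          "locus_label": "PTPRJ",
          "risk_allele_frequency": 0.48342504840759015,
          "iop_effect_mmhg": 0.1694500755605397
        }
      ],
      "allow_monomorphic": false
    },
    "baseline_iop_mmhg": 13.312181288957635,
    "age_effect_per_year": -0.02,
    "male_effect_mmhg": 1.0,
    "age_reference_years": 65.0,
    "iop_noise": {
      "family": "normal",
      "sd": 2.644822644848581
    },
    "htg_tail": {
      "family": "lognormal",
      "mu": 0.9750084997858526,
      "sigma": 1.1679557018584954
    },
    "glaucoma_iop_shift_mmhg": 4.705820932353752,
    "vulnerability_prevalence": 0.3,
    "vcdr_model": {
      "intercept": 0.46557152114486855,
      "iop_slope": 0.0008568445764258192,
      "glaucoma_offset": 0.3601208983002195,
      "noise_sd": 0.11868942392238196
    },
    "group_profiles": {
      "control": {
        "age_mean": 67.7,
        "age_sd": 11.2,
        "male_fraction": 0.366
      },
      "NTG": {
        "age_mean": 63.8,
        "age_sd": 13.3,
        "male_fraction": 0.391
      },
      "HTG": {
        "age_mean": 63.7,
        "age_sd": 14.2,
        "male_fraction": 0.612
      },
      "population": {
        "age_mean": 65.0,
        "age_sd": 13.0,
        "male_fraction": 0.45
      }
    },
    "quotas": {
      "control": 246,
      "ntg": 261,
      "htg": 255
    },
    "seed": 0,
    "attempt_cap_multiple": 1000
  },
  "calibration": {
    "n_eligible_per_group": 20000,
    "verification_seeds": [
      7,
      11,
      101
    ],
    "targets": {
      "control_mean_iop": {
        "value": 15.0,
        "tolerance": 0.05,
        "achieved": 14.950208333333334
      },
      "ntg_mean_iop": {
        "value": 18.4,
        "tolerance": 0.05,
        "achieved": 18.394984999999995
      },
      "htg_mean_iop": {
        "value": 28.6,
        "tolerance": 0.1,
        "achieved": 28.65708166666667
      },
      "control_sd_iop": {
        "value": 2.6,
        "tolerance": 0.1,
        "achieved": 2.604664480526399
      },
      "htg_sd_iop": {
        "value": 8.3,
        "tolerance": 0.3,
        "achieved": 8.92421533300512
      },
      "control_mean_grs": {
        "value": 8.7,
        "tolerance": 0.03,
        "achieved": 8.700666666666665
      },
      "htg_mean_grs": {
        "value": 9.1,
        "tolerance": 0.03,
        "achieved": 9.0675
      },
      "control_mean_vcdr": {
        "value": 0.34,
        "tolerance": 0.01,
        "achieved": 0.332816
      },
      "ntg_mean_vcdr": {
        "value": 0.83,
        "tolerance": 0.01,
        "achieved": 0.8369033333333332
      },
      "htg_mean_vcdr": {
        "value": 0.85,
        "tolerance": 0.01,
        "achieved": 0.8443348333333334
      },
      "pooled_vcdr_iop_beta": {
        "value": 0.48,
        "tolerance": 0.01,
        "achieved": 0.47902018157363196
      }
    }
  }
}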