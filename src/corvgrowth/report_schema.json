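{
  "$defs": {
    "FitRecord": {
      "properties": {
        "model": {
          "title": "Model",
          "type": "string"
        },
        "params": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Params",
          "type": "object"
        },
        "rss": {
          "title": "Rss",
          "type": "number"
        },
        "n": {
          "title": "N",
          "type": "integer"
        },
        "sigma2_hat": {
          "title": "Sigma2 Hat",
          "type": "number"
        },
        "log_lik": {
          "title": "Log Lik",
          "type": "number"
        },
        "k": {
          "title": "K",
          "type": "integer"
        },
        "converged": {
          "title": "Converged",
          "type": "boolean"
        },
        "n_restarts_used": {
          "title": "N Restarts Used",
          "type": "integer"
        },
        "at_bounds": {
          "title": "At Bounds",
          "type": "boolean"
        },
        "data_provenance": {
          "title": "Data Provenance",
          "type": "string"
        },
        "conf_int": {
          "anyOf": [
            {
              "additionalProperties": {
                "items": {
                  "type": "number"
                },
                "type": "array"
              },
              "type": "object"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Conf Int"
        }
      },
      "required": [
        "model",
        "params",
        "rss",
        "n",
        "sigma2_hat",
        "log_lik",
        "k",
        "converged",
        "n_restarts_used",
        "at_bounds",
        "data_provenance"
      ],
      "title": "FitRecord",
      "type": "object"
    },
    "IndicatorSummary": {
      "properties": {
        "l_max": {
          "title": "L Max",
          "type": "number"
        },
        "froese_binohlan_linf": {
          "title": "Froese Binohlan Linf",
          "type": "number"
        },
        "linf_by_model": {
          "additionalProperties": {
            "anyOf": [
              {
                "type": "number"
              },
              {
                "type": "null"
              }
            ]
          },
          "title": "Linf By Model",
          "type": "object"
        },
        "linf_gap_by_model": {
          "additionalProperties": {
            "anyOf": [
              {
                "type": "number"
              },
              {
                "type": "null"
              }
            ]
          },
          "title": "Linf Gap By Model",
          "type": "object"
        },
        "n_age_classes": {
          "title": "N Age Classes",
          "type": "integer"
        }
      },
      "required": [
        "l_max",
        "froese_binohlan_linf",
        "linf_by_model",
        "linf_gap_by_model",
        "n_age_classes"
      ],
      "title": "IndicatorSummary",
      "type": "object"
    },
    "ScenarioRecord": {
      "properties": {
        "scenario": {
          "title": "Scenario",
          "type": "string"
        },
        "fnssbr": {
          "title": "Fnssbr",
          "type": "number"
        },
        "ypr_over_ypr_max": {
          "title": "Ypr Over Ypr Max",
          "type": "number"
        },
        "ypr_max": {
          "title": "Ypr Max",
          "type": "number"
        },
        "E_at_ypr_max": {
          "title": "E At Ypr Max",
          "type": "number"
        }
      },
      "required": [
        "scenario",
        "fnssbr",
        "ypr_over_ypr_max",
        "ypr_max",
        "E_at_ypr_max"
      ],
      "title": "ScenarioRecord",
      "type": "object"
    },
    "SelectionRecord": {
      "properties": {
        "model": {
          "title": "Model",
          "type": "string"
        },
        "k": {
          "title": "K",
          "type": "integer"
        },
        "aicc": {
          "title": "Aicc",
          "type": "number"
        },
        "delta_aicc": {
          "title": "Delta Aicc",
          "type": "number"
        },
        "weight": {
          "title": "Weight",
          "type": "number"
        },
        "bic": {
          "title": "Bic",
          "type": "number"
        },
        "delta_bic": {
          "title": "Delta Bic",
          "type": "number"
        }
      },
      "required": [
        "model",
        "k",
        "aicc",
        "delta_aicc",
        "weight",
        "bic",
        "delta_bic"
      ],
      "title": "SelectionRecord",
      "type": "object"
    }
  },
  "description": "Machine-readable record of one full analysis run.",
  "properties": {
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "data_path": {
      "title": "Data Path",
      "type": "string"
    },
    "n_records": {
      "title": "N Records",
      "type": "integer"
    },
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "raw_fits": {
      "items": {
        "$ref": "#/$defs/FitRecord"
      },
      "title": "Raw Fits",
      "type": "array"
    },
    "raw_selection": {
      "items": {
        "$ref": "#/$defs/SelectionRecord"
      },
      "title": "Raw Selection",
      "type": "array"
    },
    "raw_model_averaged_linf": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "title": "Raw Model Averaged Linf"
    },
    "bolstered_fits": {
      "items": {
        "$ref": "#/$defs/FitRecord"
      },
      "title": "Bolstered Fits",
      "type": "array"
    },
    "bolstered_selection": {
      "items": {
        "$ref": "#/$defs/SelectionRecord"
      },
      "title": "Bolstered Selection",
      "type": "array"
    },
    "bolstered_model_averaged_linf": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "title": "Bolstered Model Averaged Linf"
    },
    "indicator_summary": {
      "$ref": "#/$defs/IndicatorSummary"
    },
    "per_recruit_summary": {
      "anyOf": [
        {
          "items": {
            "$ref": "#/$defs/ScenarioRecord"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Per Recruit Summary"
    },
    "outputs": {
      "items": {
        "type": "string"
      },
      "title": "Outputs",
      "type": "array"
    }
  },
  "required": [
    "seed",
    "data_path",
    "n_records",
    "config",
    "raw_fits",
    "raw_selection",
    "raw_model_averaged_linf",
    "bolstered_fits",
    "bolstered_selection",
    "bolstered_model_averaged_linf",
    "indicator_summary",
    "outputs"
  ],
  "title": "AnalysisReport",
  "type": "object"
}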