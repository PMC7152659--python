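{
  "$defs": {
    "ContourSummary": {
      "properties": {
        "parameter": {
          "title": "Parameter",
          "type": "string"
        },
        "lower": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Lower"
        },
        "upper": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Upper"
        },
        "threshold": {
          "title": "Threshold",
          "type": "number"
        },
        "lower_bounded_only": {
          "default": false,
          "title": "Lower Bounded Only",
          "type": "boolean"
        }
      },
      "required": [
        "parameter",
        "lower",
        "upper",
        "threshold"
      ],
      "title": "ContourSummary",
      "type": "object"
    },
    "DerivedConstants": {
      "properties": {
        "kcat": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Kcat"
        },
        "kcat_se": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Kcat Se"
        },
        "Km": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Km"
        },
        "Km_se": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Km Se"
        },
        "Ks": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ks"
        },
        "Ks_se": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ks Se"
        },
        "kcat_over_Km": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Kcat Over Km"
        },
        "kcat_over_Km_se": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Kcat Over Km Se"
        },
        "rate_limiting_step": {
          "items": {
            "type": "string"
          },
          "title": "Rate Limiting Step",
          "type": "array"
        }
      },
      "title": "DerivedConstants",
      "type": "object"
    }
  },
  "properties": {
    "kind": {
      "default": "fit",
      "title": "Kind",
      "type": "string"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "config_hash": {
      "title": "Config Hash",
      "type": "string"
    },
    "scheme": {
      "title": "Scheme",
      "type": "string"
    },
    "estimates": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Estimates",
      "type": "object"
    },
    "standard_errors": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Standard Errors",
      "type": "object"
    },
    "chi2_min": {
      "title": "Chi2 Min",
      "type": "number"
    },
    "n_points": {
      "title": "N Points",
      "type": "integer"
    },
    "n_params": {
      "title": "N Params",
      "type": "integer"
    },
    "converged": {
      "title": "Converged",
      "type": "boolean"
    },
    "identifiability_flags": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Identifiability Flags",
      "type": "object"
    },
    "derived": {
      "$ref": "#/$defs/DerivedConstants"
    },
    "contours": {
      "items": {
        "$ref": "#/$defs/ContourSummary"
      },
      "title": "Contours",
      "type": "array"
    }
  },
  "required": [
    "seed",
    "config_hash",
    "scheme",
    "estimates",
    "standard_errors",
    "chi2_min",
    "n_points",
    "n_params",
    "converged"
  ],
  "title": "FitReport",
  "type": "object"
}
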