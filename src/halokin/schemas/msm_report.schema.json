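{
  "properties": {
    "kind": {
      "default": "msm",
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
    "lag": {
      "title": "Lag",
      "type": "integer"
    },
    "n_states": {
      "title": "N States",
      "type": "integer"
    },
    "dropped_states": {
      "items": {
        "type": "integer"
      },
      "title": "Dropped States",
      "type": "array"
    },
    "equilibrium_distribution": {
      "items": {
        "type": "number"
      },
      "title": "Equilibrium Distribution",
      "type": "array"
    },
    "implied_timescales": {
      "additionalProperties": {
        "items": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ]
        },
        "type": "array"
      },
      "title": "Implied Timescales",
      "type": "object"
    },
    "ck_max_discrepancy": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Ck Max Discrepancy",
      "type": "object"
    },
    "channel_fractions": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Channel Fractions",
      "type": "object"
    },
    "nac_fraction": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Nac Fraction"
    }
  },
  "required": [
    "seed",
    "config_hash",
    "lag",
    "n_states",
    "equilibrium_distribution"
  ],
  "title": "MsmReport",
  "type": "object"
}
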