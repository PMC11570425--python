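{
  "$defs": {
    "AnalysisModel": {
      "properties": {
        "balanced": {
          "title": "Balanced",
          "type": "boolean"
        },
        "cell_counts": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Cell Counts",
          "type": "object"
        },
        "contrasts": {
          "items": {
            "$ref": "#/$defs/ContrastModel"
          },
          "title": "Contrasts",
          "type": "array"
        },
        "effects": {
          "items": {
            "$ref": "#/$defs/EffectModel"
          },
          "title": "Effects",
          "type": "array"
        },
        "gg_epsilon": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Gg Epsilon"
        },
        "mauchly_p": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Mauchly P"
        },
        "mauchly_w": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Mauchly W"
        },
        "n_subjects": {
          "title": "N Subjects",
          "type": "integer"
        },
        "name": {
          "title": "Name",
          "type": "string"
        }
      },
      "required": [
        "name",
        "n_subjects",
        "cell_counts",
        "balanced",
        "effects",
        "contrasts"
      ],
      "title": "AnalysisModel",
      "type": "object"
    },
    "ContrastModel": {
      "properties": {
        "adjustment": {
          "title": "Adjustment",
          "type": "string"
        },
        "cohen_d": {
          "title": "Cohen D",
          "type": "number"
        },
        "df": {
          "title": "Df",
          "type": "number"
        },
        "estimate": {
          "title": "Estimate",
          "type": "number"
        },
        "group": {
          "title": "Group",
          "type": "string"
        },
        "level_a": {
          "title": "Level A",
          "type": "string"
        },
        "level_b": {
          "title": "Level B",
          "type": "string"
        },
        "n": {
          "title": "N",
          "type": "integer"
        },
        "p_adj": {
          "title": "P Adj",
          "type": "number"
        },
        "p_unc": {
          "title": "P Unc",
          "type": "number"
        },
        "t": {
          "title": "T",
          "type": "number"
        }
      },
      "required": [
        "group",
        "level_a",
        "level_b",
        "estimate",
        "t",
        "df",
        "p_unc",
        "p_adj",
        "adjustment",
        "cohen_d",
        "n"
      ],
      "title": "ContrastModel",
      "type": "object"
    },
    "EffectModel": {
      "properties": {
        "F": {
          "title": "F",
          "type": "number"
        },
        "bf_incl": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Bf Incl"
        },
        "df_den": {
          "title": "Df Den",
          "type": "number"
        },
        "df_num": {
          "title": "Df Num",
          "type": "number"
        },
        "effect": {
          "title": "Effect",
          "type": "string"
        },
        "gg_applied": {
          "default": false,
          "title": "Gg Applied",
          "type": "boolean"
        },
        "gg_epsilon": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Gg Epsilon"
        },
        "p_gg": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "P Gg"
        },
        "p_unc": {
          "title": "P Unc",
          "type": "number"
        },
        "partial_eta_sq": {
          "title": "Partial Eta Sq",
          "type": "number"
        }
      },
      "required": [
        "effect",
        "df_num",
        "df_den",
        "F",
        "p_unc",
        "partial_eta_sq"
      ],
      "title": "EffectModel",
      "type": "object"
    }
  },
  "description": "Top-level analysis report written by the pipeline as report.json.",
  "properties": {
    "analyses": {
      "items": {
        "$ref": "#/$defs/AnalysisModel"
      },
      "title": "Analyses",
      "type": "array"
    },
    "exclusions": {
      "items": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Exclusions",
      "type": "array"
    },
    "flags": {
      "items": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Flags",
      "type": "array"
    },
    "n_blocks_scored": {
      "title": "N Blocks Scored",
      "type": "integer"
    },
    "n_participants": {
      "title": "N Participants",
      "type": "integer"
    },
    "seed": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Seed"
    }
  },
  "required": [
    "n_participants",
    "n_blocks_scored",
    "exclusions",
    "flags",
    "analyses"
  ],
  "title": "StudyReport",
  "type": "object"
}
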