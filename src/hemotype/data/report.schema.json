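{
  "$defs": {
    "CoverageCall": {
      "properties": {
        "rule_id": {
          "title": "Rule Id",
          "type": "string"
        },
        "status": {
          "title": "Status",
          "type": "string"
        },
        "target_mean": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Target Mean"
        },
        "control_mean": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Control Mean"
        },
        "ratio": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ratio"
        },
        "copy_number": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Copy Number"
        },
        "label": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Label"
        },
        "reason": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Reason"
        }
      },
      "required": [
        "rule_id",
        "status"
      ],
      "title": "CoverageCall",
      "type": "object"
    },
    "Provenance": {
      "properties": {
        "catalog_checksum": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Catalog Checksum"
        },
        "inputs": {
          "additionalProperties": {
            "type": "string"
          },
          "title": "Inputs",
          "type": "object"
        },
        "parameters": {
          "additionalProperties": {
            "type": "string"
          },
          "title": "Parameters",
          "type": "object"
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
      "title": "Provenance",
      "type": "object"
    },
    "SystemCall": {
      "description": "One system's diplotype call, with grouped (reporting) allele names.",
      "properties": {
        "best_pairs": {
          "items": {
            "maxItems": 2,
            "minItems": 2,
            "prefixItems": [
              {
                "type": "string"
              },
              {
                "type": "string"
              }
            ],
            "type": "array"
          },
          "title": "Best Pairs",
          "type": "array"
        },
        "best_score": {
          "title": "Best Score",
          "type": "number"
        },
        "ambiguous": {
          "title": "Ambiguous",
          "type": "boolean"
        },
        "no_call": {
          "title": "No Call",
          "type": "boolean"
        },
        "antigen_phenotype": {
          "items": {
            "type": "string"
          },
          "title": "Antigen Phenotype",
          "type": "array"
        },
        "all_scores": {
          "anyOf": [
            {
              "items": {
                "maxItems": 2,
                "minItems": 2,
                "prefixItems": [
                  {
                    "maxItems": 2,
                    "minItems": 2,
                    "prefixItems": [
                      {
                        "type": "string"
                      },
                      {
                        "type": "string"
                      }
                    ],
                    "type": "array"
                  },
                  {
                    "type": "number"
                  }
                ],
                "type": "array"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "All Scores"
        }
      },
      "required": [
        "best_pairs",
        "best_score",
        "ambiguous",
        "no_call",
        "antigen_phenotype"
      ],
      "title": "SystemCall",
      "type": "object"
    }
  },
  "properties": {
    "schema_version": {
      "default": "1.0",
      "title": "Schema Version",
      "type": "string"
    },
    "sample_id": {
      "title": "Sample Id",
      "type": "string"
    },
    "systems": {
      "additionalProperties": {
        "$ref": "#/$defs/SystemCall"
      },
      "title": "Systems",
      "type": "object"
    },
    "coverage_calls": {
      "items": {
        "$ref": "#/$defs/CoverageCall"
      },
      "title": "Coverage Calls",
      "type": "array"
    },
    "provenance": {
      "$ref": "#/$defs/Provenance"
    }
  },
  "required": [
    "sample_id",
    "systems"
  ],
  "title": "Report",
  "type": "object"
}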