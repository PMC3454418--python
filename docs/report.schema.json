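{
  "$defs": {
    "CorpusSummary": {
      "properties": {
        "tokens": {
          "title": "Tokens",
          "type": "integer"
        },
        "bouts": {
          "title": "Bouts",
          "type": "integer"
        },
        "repertoire_size": {
          "title": "Repertoire Size",
          "type": "integer"
        },
        "source_id": {
          "default": "",
          "title": "Source Id",
          "type": "string"
        }
      },
      "required": [
        "tokens",
        "bouts",
        "repertoire_size"
      ],
      "title": "CorpusSummary",
      "type": "object"
    },
    "EnsembleStat": {
      "properties": {
        "measure": {
          "title": "Measure",
          "type": "string"
        },
        "observed": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Observed"
        },
        "mean": {
          "title": "Mean",
          "type": "number"
        },
        "sd": {
          "title": "Sd",
          "type": "number"
        },
        "z": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Z"
        }
      },
      "required": [
        "measure",
        "mean",
        "sd"
      ],
      "title": "EnsembleStat",
      "type": "object"
    },
    "Provenance": {
      "properties": {
        "seed": {
          "title": "Seed",
          "type": "integer"
        },
        "reps": {
          "title": "Reps",
          "type": "integer"
        },
        "version": {
          "title": "Version",
          "type": "string"
        },
        "timestamp": {
          "title": "Timestamp",
          "type": "string"
        }
      },
      "required": [
        "seed",
        "reps",
        "version",
        "timestamp"
      ],
      "title": "Provenance",
      "type": "object"
    },
    "SdnBlock": {
      "properties": {
        "n": {
          "title": "N",
          "type": "integer"
        },
        "arcs": {
          "title": "Arcs",
          "type": "integer"
        },
        "L": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "L"
        },
        "mean_total_degree": {
          "title": "Mean Total Degree",
          "type": "number"
        },
        "motif_counts": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Motif Counts",
          "type": "object"
        },
        "motif_proportions": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Motif Proportions",
          "type": "object"
        },
        "rdn_ensemble": {
          "default": [],
          "items": {
            "$ref": "#/$defs/EnsembleStat"
          },
          "title": "Rdn Ensemble",
          "type": "array"
        },
        "chi2": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Chi2"
        },
        "df": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Df"
        },
        "pvalue": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Pvalue"
        }
      },
      "required": [
        "n",
        "arcs",
        "L",
        "mean_total_degree",
        "motif_counts",
        "motif_proportions"
      ],
      "title": "SdnBlock",
      "type": "object"
    },
    "SunBlock": {
      "properties": {
        "n": {
          "title": "N",
          "type": "integer"
        },
        "edges": {
          "title": "Edges",
          "type": "integer"
        },
        "L": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "L"
        },
        "C": {
          "title": "C",
          "type": "number"
        },
        "mean_degree": {
          "title": "Mean Degree",
          "type": "number"
        },
        "degree_histogram": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Degree Histogram",
          "type": "object"
        },
        "S": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "S"
        },
        "run_ensemble": {
          "default": [],
          "items": {
            "$ref": "#/$defs/EnsembleStat"
          },
          "title": "Run Ensemble",
          "type": "array"
        }
      },
      "required": [
        "n",
        "edges",
        "L",
        "C",
        "mean_degree",
        "degree_histogram"
      ],
      "title": "SunBlock",
      "type": "object"
    }
  },
  "description": "Serializable result of one full song-network analysis.",
  "properties": {
    "corpus": {
      "$ref": "#/$defs/CorpusSummary"
    },
    "sun": {
      "$ref": "#/$defs/SunBlock"
    },
    "sdn": {
      "$ref": "#/$defs/SdnBlock"
    },
    "provenance": {
      "$ref": "#/$defs/Provenance"
    }
  },
  "required": [
    "corpus",
    "sun",
    "sdn",
    "provenance"
  ],
  "title": "AnalysisReport",
  "type": "object"
}
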