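{
 "$defs": {
  "ChiSquareStageReport": {
   "properties": {
    "chi2": {
     "title": "Chi2",
     "type": "number"
    },
    "df": {
     "title": "Df",
     "type": "integer"
    },
    "p_value": {
     "title": "P Value",
     "type": "number"
    }
   },
   "required": [
    "chi2",
    "df",
    "p_value"
   ],
   "title": "ChiSquareStageReport",
   "type": "object"
  },
  "ClusteringStageReport": {
   "properties": {
    "subset": {
     "title": "Subset",
     "type": "string"
    },
    "n_genes": {
     "title": "N Genes",
     "type": "integer"
    },
    "per_chromosome_counts": {
     "additionalProperties": {
      "type": "integer"
     },
     "title": "Per Chromosome Counts",
     "type": "object"
    },
    "ks": {
     "$ref": "#/$defs/KSStageReport"
    },
    "chisq_vs_high_cpg": {
     "anyOf": [
      {
       "$ref": "#/$defs/ChiSquareStageReport"
      },
      {
       "type": "null"
      }
     ],
     "default": null
    },
    "centromere_proximal": {
     "anyOf": [
      {
       "additionalProperties": {
        "anyOf": [
         {
          "type": "integer"
         },
         {
          "type": "null"
         }
        ]
       },
       "type": "object"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Centromere Proximal"
    },
    "centromere_window_bp": {
     "anyOf": [
      {
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Centromere Window Bp"
    }
   },
   "required": [
    "subset",
    "n_genes",
    "per_chromosome_counts",
    "ks"
   ],
   "title": "ClusteringStageReport",
   "type": "object"
  },
  "CpGStageReport": {
   "properties": {
    "n_genes": {
     "title": "N Genes",
     "type": "integer"
    },
    "n_undefined": {
     "title": "N Undefined",
     "type": "integer"
    },
    "mean": {
     "title": "Mean",
     "type": "number"
    },
    "sd": {
     "title": "Sd",
     "type": "number"
    },
    "min": {
     "title": "Min",
     "type": "number"
    },
    "max": {
     "title": "Max",
     "type": "number"
    },
    "percent_below_threshold": {
     "title": "Percent Below Threshold",
     "type": "number"
    },
    "threshold": {
     "title": "Threshold",
     "type": "number"
    },
    "n_modes": {
     "title": "N Modes",
     "type": "integer"
    },
    "tail_size": {
     "title": "Tail Size",
     "type": "integer"
    }
   },
   "required": [
    "n_genes",
    "n_undefined",
    "mean",
    "sd",
    "min",
    "max",
    "percent_below_threshold",
    "threshold",
    "n_modes",
    "tail_size"
   ],
   "title": "CpGStageReport",
   "type": "object"
  },
  "DepthStageReport": {
   "properties": {
    "n_genes": {
     "title": "N Genes",
     "type": "integer"
    },
    "n_outliers_high": {
     "title": "N Outliers High",
     "type": "integer"
    },
    "percent_outliers": {
     "title": "Percent Outliers",
     "type": "number"
    },
    "q1": {
     "title": "Q1",
     "type": "number"
    },
    "q3": {
     "title": "Q3",
     "type": "number"
    }
   },
   "required": [
    "n_genes",
    "n_outliers_high",
    "percent_outliers",
    "q1",
    "q3"
   ],
   "title": "DepthStageReport",
   "type": "object"
  },
  "EnrichmentStageReport": {
   "properties": {
    "n_terms_tested": {
     "title": "N Terms Tested",
     "type": "integer"
    },
    "n_significant": {
     "title": "N Significant",
     "type": "integer"
    },
    "alpha": {
     "title": "Alpha",
     "type": "number"
    },
    "top_terms": {
     "items": {
      "type": "string"
     },
     "title": "Top Terms",
     "type": "array"
    }
   },
   "required": [
    "n_terms_tested",
    "n_significant",
    "alpha",
    "top_terms"
   ],
   "title": "EnrichmentStageReport",
   "type": "object"
  },
  "KSStageReport": {
   "properties": {
    "D": {
     "title": "D",
     "type": "number"
    },
    "p_value": {
     "title": "P Value",
     "type": "number"
    },
    "n": {
     "title": "N",
     "type": "integer"
    },
    "null_mode": {
     "title": "Null Mode",
     "type": "string"
    }
   },
   "required": [
    "D",
    "p_value",
    "n",
    "null_mode"
   ],
   "title": "KSStageReport",
   "type": "object"
  },
  "KsStageReport": {
   "properties": {
    "n_pairs": {
     "title": "N Pairs",
     "type": "integer"
    },
    "n_saturated": {
     "title": "N Saturated",
     "type": "integer"
    },
    "mean_ks": {
     "title": "Mean Ks",
     "type": "number"
    },
    "window_fractions": {
     "additionalProperties": {
      "type": "number"
     },
     "title": "Window Fractions",
     "type": "object"
    }
   },
   "required": [
    "n_pairs",
    "n_saturated",
    "mean_ks",
    "window_fractions"
   ],
   "title": "KsStageReport",
   "type": "object"
  }
 },
 "properties": {
  "version": {
   "title": "Version",
   "type": "string"
  },
  "seed": {
   "title": "Seed",
   "type": "integer"
  },
  "input_hashes": {
   "additionalProperties": {
    "type": "string"
   },
   "title": "Input Hashes",
   "type": "object"
  },
  "parameters": {
   "additionalProperties": true,
   "title": "Parameters",
   "type": "object"
  },
  "cpg": {
   "anyOf": [
    {
     "$ref": "#/$defs/CpGStageReport"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "enrichment": {
   "anyOf": [
    {
     "$ref": "#/$defs/EnrichmentStageReport"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "clustering": {
   "anyOf": [
    {
     "$ref": "#/$defs/ClusteringStageReport"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "depth": {
   "anyOf": [
    {
     "$ref": "#/$defs/DepthStageReport"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "ks": {
   "anyOf": [
    {
     "$ref": "#/$defs/KsStageReport"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "skipped": {
   "default": [],
   "items": {
    "type": "string"
   },
   "title": "Skipped",
   "type": "array"
  }
 },
 "required": [
  "version",
  "seed",
  "input_hashes",
  "parameters"
 ],
 "title": "RunReport",
 "type": "object"
}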