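{
  "type": "object",
  "required": ["settings", "network", "sets", "wmw", "logistic"],
  "properties": {
    "settings": {
      "type": "object",
      "required": ["alpha", "k_bins", "prom_transform", "cod_transform"],
      "properties": {
        "alpha": {"type": "number"},
        "k_bins": {"type": "integer"},
        "top_k": {"type": "integer"},
        "prom_transform": {"type": "string"},
        "cod_transform": {"type": "string"},
        "include_positives_in_reference": {"type": "boolean"}
      }
    },
    "network": {
      "type": "object",
      "required": ["n_nodes", "n_edges", "component_nodes", "component_edges"],
      "properties": {
        "n_nodes": {"type": "integer"},
        "n_edges": {"type": "integer"},
        "component_nodes": {"type": "integer"},
        "component_edges": {"type": "integer"}
      }
    },
    "sets": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["study", "reference"],
        "properties": {
          "study": {"type": "integer"},
          "reference": {"type": "integer"}
        }
      }
    },
    "wmw": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "additionalProperties": {
          "type": "object",
          "required": ["p", "alternative"],
          "properties": {
            "p": {"type": "number"},
            "alternative": {"type": "string"},
            "study_median": {"type": "number"},
            "reference_median": {"type": "number"},
            "method": {"type": "string"}
          }
        }
      }
    },
    "logistic": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["transform", "n"],
        "properties": {
          "coefficient": {"type": ["number", "null"]},
          "stderr": {"type": ["number", "null"]},
          "p": {"type": ["number", "null"]},
          "transform": {"type": "string"},
          "n": {"type": "integer"},
          "separated": {"type": "boolean"}
        }
      }
    },
    "quantile_bins": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["upper_quantile", "frequency", "n"],
        "properties": {
          "upper_quantile": {"type": "array", "items": {"type": "number"}},
          "frequency": {"type": "array", "items": {"type": "number"}},
          "n": {"type": "array", "items": {"type": "integer"}}
        }
      }
    },
    "top_central": {
      "type": "object",
      "additionalProperties": {"type": "array", "items": {"type": "string"}}
    },
    "enrichment": {"type": "object"},
    "expression": {"type": "object"}
  }
}
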