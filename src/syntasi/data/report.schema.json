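{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "syntasi phasing/processing report",
  "type": "object",
  "required": ["design", "profile", "processing_accuracy", "phasing", "provenance"],
  "properties": {
    "design": {
      "type": "object",
      "required": ["name", "length", "n_guides", "cleavage_position"],
      "properties": {
        "name": {"type": "string"},
        "length": {"type": "integer", "minimum": 54},
        "n_guides": {"type": "integer", "minimum": 1},
        "cleavage_position": {"type": "integer", "const": 12}
      }
    },
    "profile": {
      "type": "object",
      "required": ["size_range", "total_mapped", "rpm_denominator"],
      "properties": {
        "size_range": {"type": "array", "items": {"type": "integer"}, "minItems": 2, "maxItems": 2},
        "total_mapped": {"type": "integer", "minimum": 0},
        "rpm_denominator": {"type": "integer", "minimum": 0}
      }
    },
    "processing_accuracy": {
      "type": "object",
      "required": ["window", "per_guide", "pooled"],
      "properties": {
        "window": {"type": "integer", "minimum": 0},
        "per_guide": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["guide", "guide_index", "guide_position", "window_count", "authentic_count", "fraction"],
            "properties": {
              "guide": {"type": "string"},
              "guide_index": {"type": "integer", "minimum": 1},
              "guide_position": {"type": "integer", "minimum": 1},
              "window_count": {"type": "integer", "minimum": 0},
              "authentic_count": {"type": "integer", "minimum": 0},
              "fraction": {"type": ["number", "null"], "minimum": 0, "maximum": 1}
            }
          }
        },
        "pooled": {
          "type": "object",
          "required": ["window_count", "authentic_count", "fraction"],
          "properties": {
            "window_count": {"type": "integer", "minimum": 0},
            "authentic_count": {"type": "integer", "minimum": 0},
            "fraction": {"type": ["number", "null"], "minimum": 0, "maximum": 1}
          }
        }
      }
    },
    "phasing": {
      "type": "object",
      "required": ["n_reads", "register_counts", "register_proportion"],
      "properties": {
        "n_reads": {"type": "integer", "minimum": 0},
        "register_counts": {"type": "array", "items": {"type": "integer", "minimum": 0}, "minItems": 21, "maxItems": 21},
        "register_proportion": {"type": "array", "items": {"type": "number", "minimum": 0, "maximum": 1}, "minItems": 21, "maxItems": 21}
      }
    },
    "provenance": {"type": "object"}
  }
}
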