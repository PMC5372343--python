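{
  "$comment": "Machine report written by the pipeline (report.json)",
  "type": "object",
  "required": ["groups", "pairs"],
  "properties": {
    "groups": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "strains"],
        "properties": {
          "id": {"type": "integer"},
          "strains": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "pairs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["sG", "cG", "inv_d", "r_d", "inversions"],
        "properties": {
          "sG": {"type": "integer"},
          "cG": {"type": "integer"},
          "inv_d": {"type": "integer"},
          "r_d": {"type": "integer"},
          "event_counts": {"type": "object"},
          "inversions": {"type": "array"}
        }
      }
    },
    "prevalence": {"type": ["object", "null"]}
  }
}
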