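{
  "$comment": "Truth log emitted by the synthetic-data generator",
  "type": "object",
  "required": ["ancestor_scaffold", "events"],
  "properties": {
    "ancestor_scaffold": {"type": "array", "items": {"type": "integer"}},
    "events": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["strain", "kind", "repeat_label", "copies",
                     "repeat_coords", "scaffold_before", "scaffold_after"],
        "properties": {
          "strain": {"type": "string"},
          "kind": {"type": "string"},
          "tag": {"type": "string"},
          "repeat_label": {"type": "string"},
          "copies": {"type": "array", "items": {"type": "integer"}},
          "repeat_coords": {"type": "array"},
          "scaffold_before": {"type": "array", "items": {"type": "integer"}},
          "scaffold_after": {"type": "array", "items": {"type": "integer"}}
        }
      }
    }
  }
}
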