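{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "qstrip pairwise comparison report",
  "type": "object",
  "required": [
    "ref_id",
    "cmp_id",
    "length",
    "padded_length",
    "n_pad",
    "method",
    "p1",
    "similarity"
  ],
  "properties": {
    "ref_id": {"type": "string"},
    "cmp_id": {"type": "string"},
    "length": {"type": "integer", "minimum": 1},
    "padded_length": {"type": "integer", "minimum": 1},
    "n_pad": {"type": "integer", "minimum": 0},
    "method": {"type": "string", "enum": ["analytic", "statevector", "shots"]},
    "p1": {"type": "number", "minimum": 0, "maximum": 1},
    "similarity": {"type": "number", "minimum": -1, "maximum": 1},
    "similarity_corrected": {"type": ["number", "null"], "minimum": -1, "maximum": 1},
    "shots": {"type": "integer", "minimum": 1},
    "seed": {"type": "integer"},
    "counts": {"type": "object"}
  }
}
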