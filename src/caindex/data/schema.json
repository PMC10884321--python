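{
 "$schema": "http://json-schema.org/draft-07/schema#",
 "title": "caindex character table",
 "description": "JSON form of a species x structure character table. Component lists are strings joined with ' | '. This schema documents the format; the package validates in code.",
 "type": "object",
 "required": ["species"],
 "properties": {
  "species": {
   "type": "array",
   "minItems": 1,
   "items": {
    "type": "object",
    "required": ["name", "palmar_arches", "structures"],
    "properties": {
     "name": {"type": "string", "minLength": 1},
     "palmar_arches": {"enum": [1, 2]},
     "structures": {
      "type": "array",
      "minItems": 1,
      "items": {
       "type": "object",
       "required": ["group", "structure", "count_low", "count_high", "r_v", "n"],
       "properties": {
        "group": {"enum": ["central", "hypothenar", "thenar"]},
        "structure": {"type": "string", "minLength": 1},
        "innervation": {"type": "string"},
        "origin": {"type": "string"},
        "insertion": {"type": "string"},
        "supply": {"type": "string"},
        "count_low": {"type": "number", "minimum": 0},
        "count_high": {"type": "number", "minimum": 0},
        "r_v": {"type": "integer", "minimum": 0},
        "n": {"type": "integer", "minimum": 1},
        "variant_frequency": {"type": ["number", "string", "null"]}
       }
      }
     }
    }
   }
  }
 }
}
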