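{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "wildfuse run configuration (YAML)",
 "type": "object",
 "additionalProperties": false,
 "properties": {
  "n_scenes": {"type": "integer", "minimum": 1},
  "methods": {
   "type": "array",
   "items": {
    "enum": ["guided_filter", "laplacian", "svd", "sparse", "gradient", "tvm", "wl_tvm", "wl_swarm"]
   }
  },
  "entropy_bins": {"type": "integer", "minimum": 2},
  "mi_bins": {"type": "integer", "minimum": 2},
  "iou_threshold": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
  "include_published_ranking": {"type": "boolean"},
  "out_dir": {"type": "string"},
  "seed": {"type": "integer"},
  "scene": {
   "type": "object",
   "additionalProperties": false,
   "properties": {
    "visible_dims": {"$ref": "#/$defs/dims"},
    "thermal_dims": {"$ref": "#/$defs/dims"},
    "misregistration": {
     "type": "object",
     "properties": {
      "scale": {"type": "number", "exclusiveMinimum": 0},
      "tx": {"type": "number"},
      "ty": {"type": "number"}
     },
     "required": ["scale"]
    },
    "background_smoothness": {"type": "number", "minimum": 0},
    "noise_sigma": {"type": "number", "minimum": 0},
    "thermal_background_level": {"type": "number", "minimum": 0, "maximum": 1},
    "seed": {"type": "integer"},
    "species": {
     "type": "array",
     "items": {
      "type": "object",
      "properties": {
       "name": {"type": "string"},
       "visible_contrast": {"type": "number", "minimum": -1, "maximum": 1},
       "thermal_contrast": {"type": "number", "minimum": 0, "maximum": 1},
       "size_range": {"$ref": "#/$defs/range"},
       "shadow_prob": {"type": "number", "minimum": 0, "maximum": 1},
       "count_range": {"$ref": "#/$defs/range"}
      },
      "required": ["name", "visible_contrast", "thermal_contrast", "size_range", "shadow_prob", "count_range"]
     }
    }
   }
  },
  "detector": {
   "type": "object",
   "additionalProperties": false,
   "properties": {
    "fn_rate": {"type": "number", "minimum": 0, "maximum": 1},
    "fp_rate": {"type": "number", "minimum": 0, "maximum": 1},
    "loc_jitter_sigma": {"type": "number", "minimum": 0},
    "misclass_rate": {"type": "number", "minimum": 0, "maximum": 1}
   }
  }
 },
 "$defs": {
  "dims": {
   "type": "array",
   "items": {"type": "integer", "minimum": 1},
   "minItems": 2,
   "maxItems": 2
  },
  "range": {
   "type": "array",
   "items": {"type": "number"},
   "minItems": 2,
   "maxItems": 2
  }
 }
}
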