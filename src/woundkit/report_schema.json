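{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "woundkit analysis report",
  "type": "object",
  "required": ["wounds", "segmentation", "size_calibration", "provenance"],
  "properties": {
    "segmentation": {
      "type": "object",
      "required": ["ok"],
      "properties": {
        "ok": {"type": "boolean"},
        "skin_fraction": {"type": "number"},
        "reason": {"type": "string"}
      }
    },
    "size_calibration": {
      "type": "object",
      "required": ["ok"],
      "properties": {
        "ok": {"type": "boolean"},
        "marker_id": {"type": "integer"},
        "marker_side_px": {"type": "number"},
        "cm_per_px": {"type": "number"},
        "reason": {"type": "string"}
      }
    },
    "wounds": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["box", "confidence", "classification", "size", "colors", "roughness"],
        "properties": {
          "box": {"type": "array", "items": {"type": "number"}, "minItems": 4, "maxItems": 4},
          "confidence": {"type": "number", "minimum": 0, "maximum": 1},
          "classification": {
            "type": ["object", "null"],
            "required": ["p_inf", "p_isch", "p_none", "p_inf_only", "p_isch_only", "p_both", "label"],
            "properties": {
              "p_inf": {"type": "number"},
              "p_isch": {"type": "number"},
              "p_none": {"type": "number"},
              "p_inf_only": {"type": "number"},
              "p_isch_only": {"type": "number"},
              "p_both": {"type": "number"},
              "label": {"type": "string", "enum": ["none", "infection_only", "ischemia_only", "both"]}
            }
          },
          "size": {
            "type": ["object", "null"],
            "required": ["width_cm", "height_cm", "pixel_per_cm"],
            "properties": {
              "width_cm": {"type": "number"},
              "height_cm": {"type": "number"},
              "width_cm_raw": {"type": "number"},
              "height_cm_raw": {"type": "number"},
              "pixel_per_cm": {"type": "number"}
            }
          },
          "colors": {
            "type": "array",
            "minItems": 7,
            "maxItems": 7,
            "items": {
              "type": "object",
              "required": ["hex", "lab", "percent"],
              "properties": {
                "hex": {"type": "string"},
                "lab": {"type": "array", "items": {"type": "number"}},
                "percent": {"type": "number", "minimum": 0, "maximum": 100}
              }
            }
          },
          "roughness": {
            "type": "object",
            "required": ["ra", "rq"],
            "properties": {"ra": {"type": "number"}, "rq": {"type": "number"}}
          }
        }
      }
    },
    "provenance": {
      "type": "object",
      "required": ["woundkit_version", "config_hash", "config"],
      "properties": {
        "woundkit_version": {"type": "string"},
        "config_hash": {"type": "string"},
        "config": {"type": "object"}
      }
    }
  }
}
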