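{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "steatoquant quantification report",
  "type": "object",
  "required": ["schema_version", "package", "seed", "config", "fields", "slide"],
  "properties": {
    "schema_version": {"type": "integer"},
    "package": {
      "type": "object",
      "required": ["name", "version"],
      "properties": {
        "name": {"type": "string"},
        "version": {"type": "string"}
      }
    },
    "seed": {"type": "integer"},
    "config": {"type": "object"},
    "inputs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source_id"],
        "properties": {
          "source_id": {"type": "string"},
          "sha256": {"type": ["string", "null"]}
        }
      }
    },
    "fields": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source_id", "fat_px", "tissue_px", "fraction", "percent", "n_tiles", "per_tile_fractions"],
        "properties": {
          "source_id": {"type": "string"},
          "fat_px": {"type": "integer"},
          "tissue_px": {"type": "integer"},
          "fraction": {"type": "number"},
          "percent": {"type": "number"},
          "n_tiles": {"type": "integer"},
          "per_tile_fractions": {"type": "array", "items": {"type": "number"}}
        }
      }
    },
    "slide": {
      "type": "object",
      "required": ["slide_fraction", "percent", "pooled_fraction", "n_fields", "rejected_fields", "valid"],
      "properties": {
        "slide_fraction": {"type": ["number", "null"]},
        "percent": {"type": ["number", "null"]},
        "pooled_fraction": {"type": ["number", "null"]},
        "n_fields": {"type": "integer"},
        "valid": {"type": "boolean"},
        "invalid_reason": {"type": ["string", "null"]},
        "rejected_fields": {
          "type": "array",
          "items": {
            "type": "array",
            "items": {"type": "string"}
          }
        }
      }
    }
  }
}
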