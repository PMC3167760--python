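{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "glaufuse cohort",
  "description": "Descriptive schema of the glaufuse JSON cohort format. Validation is performed in code (glaufuse.cohort); this document specifies the on-disk contract.",
  "type": "object",
  "required": ["format", "version", "laterality", "records"],
  "properties": {
    "format": {"const": "glaufuse-cohort"},
    "version": {"const": 1},
    "laterality": {"const": "RIGHT_CONVENTION"},
    "metadata": {"type": "object"},
    "records": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["subject_id", "label", "sap", "oct"],
        "properties": {
          "subject_id": {"type": "string"},
          "label": {"enum": ["HEALTHY", "GLAUCOMA"]},
          "severity": {"enum": ["EARLY", "MODERATE", "ADVANCED", null]},
          "sap": {
            "type": "object",
            "required": ["pd_categories", "md_db", "ght_label"],
            "properties": {
              "pd_categories": {
                "type": "array",
                "minItems": 52,
                "maxItems": 52,
                "items": {"enum": ["GE5", "LT5", "LT2", "LT1", "LT05"]},
                "description": "Pattern-deviation categories in canonical 24-2 grid order (rows superior to inferior, x ascending)."
              },
              "md_db": {"type": "number"},
              "ght_label": {"enum": ["WNL", "BORDERLINE", "ONL"]}
            }
          },
          "oct": {
            "type": "object",
            "required": ["ascan_um", "signal_strength", "age_years", "se_diopters"],
            "properties": {
              "ascan_um": {
                "type": "array",
                "minItems": 256,
                "maxItems": 256,
                "items": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 400},
                "description": "RNFL thickness in µm, TSNIT order, index 0 at the temporal meridian proceeding superiorly."
              },
              "signal_strength": {"type": "integer", "minimum": 0, "maximum": 10},
              "age_years": {"type": "number"},
              "se_diopters": {"type": "number"}
            }
          }
        }
      }
    }
  }
}
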