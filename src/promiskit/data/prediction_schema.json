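{
  "$comment": "Schema (version 1) of the predictions JSON written by promiskit. Validated by promiskit.prediction_engine.validate_predictions_payload.",
  "type": "object",
  "required": ["schema_version", "predictions"],
  "properties": {
    "schema_version": {"const": 1},
    "predictions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["query", "product", "co_products", "template", "rule_id", "centre_atoms"],
        "properties": {
          "query": {
            "type": "object",
            "required": ["id", "name", "smiles"],
            "properties": {
              "id": {"type": "string"},
              "name": {"type": "string"},
              "smiles": {"type": "string"}
            }
          },
          "product": {
            "type": "object",
            "required": ["smiles", "molblock"],
            "properties": {
              "smiles": {"type": "string"},
              "molblock": {"type": "string"}
            }
          },
          "co_products": {"type": "array", "items": {"type": "string"}},
          "template": {
            "type": "object",
            "required": ["reaction_id", "ec", "equation"],
            "properties": {
              "reaction_id": {"type": "string"},
              "ec": {"type": "array", "items": {"type": "string"}},
              "equation": {"type": "string"}
            }
          },
          "rule_id": {"type": "string"},
          "centre_atoms": {"type": "array", "items": {"type": "integer"}}
        }
      }
    }
  }
}
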