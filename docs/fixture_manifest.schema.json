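{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "pepscout fixture manifest",
  "description": "Offline stand-in for dataset repositories: per-repository dataset metadata, planted protein->dataset associations, planted peptide->USI associations, and an optional scripted-failure table for exercising the retry contract.",
  "type": "object",
  "required": ["repositories"],
  "properties": {
    "schema": {"const": "pepscout-fixture-manifest/1"},
    "seed": {"type": "integer"},
    "repositories": {
      "type": "object",
      "minProperties": 1,
      "additionalProperties": {
        "type": "object",
        "properties": {
          "datasets": {
            "type": "object",
            "additionalProperties": {
              "type": "object",
              "properties": {
                "title": {"type": "string"},
                "summary": {"type": "string"},
                "project_url": {"type": "string"},
                "organisms": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "properties": {
                      "name": {"type": ["string", "null"]},
                      "taxon_id": {"type": ["integer", "null"]}
                    }
                  }
                }
              }
            }
          },
          "protein_index": {
            "type": "object",
            "additionalProperties": {"type": "array", "items": {"type": "string"}}
          },
          "peptide_index": {
            "type": "object",
            "additionalProperties": {
              "type": "array",
              "items": {"type": "string", "pattern": "^mzspec:"}
            }
          },
          "failures": {
            "type": "object",
            "description": "Query key ('protein:<acc>' / 'peptide:<seq>' / 'dataset:<acc>') to the number of leading exchanges that fail.",
            "additionalProperties": {"type": "integer", "minimum": 0}
          }
        }
      }
    }
  }
}
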