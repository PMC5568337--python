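{
  "description": "Per-stage results plus a cohort summary and a provenance block.",
  "properties": {
    "cohort_summary": {
      "additionalProperties": {
        "additionalProperties": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "number"
            }
          ]
        },
        "type": "object"
      },
      "title": "Cohort Summary",
      "type": "object"
    },
    "stages": {
      "additionalProperties": true,
      "title": "Stages",
      "type": "object"
    },
    "provenance": {
      "additionalProperties": true,
      "title": "Provenance",
      "type": "object"
    }
  },
  "required": [
    "cohort_summary",
    "stages",
    "provenance"
  ],
  "title": "RunReport",
  "type": "object"
}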