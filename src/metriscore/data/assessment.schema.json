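{
  "$defs": {
    "ProfileDocument": {
      "additionalProperties": false,
      "properties": {
        "uses_segmentation": {
          "title": "Uses Segmentation",
          "type": "boolean"
        },
        "fully_automated_segmentation": {
          "title": "Fully Automated Segmentation",
          "type": "boolean"
        },
        "uses_handcrafted_features": {
          "title": "Uses Handcrafted Features",
          "type": "boolean"
        },
        "uses_tabular_features": {
          "title": "Uses Tabular Features",
          "type": "boolean"
        },
        "uses_end_to_end_dl": {
          "title": "Uses End To End Dl",
          "type": "boolean"
        }
      },
      "required": [
        "uses_segmentation",
        "fully_automated_segmentation",
        "uses_handcrafted_features",
        "uses_tabular_features",
        "uses_end_to_end_dl"
      ],
      "title": "ProfileDocument",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "File-level schema of one study assessment.",
  "properties": {
    "study_id": {
      "title": "Study Id",
      "type": "string"
    },
    "profile": {
      "$ref": "#/$defs/ProfileDocument"
    },
    "statuses": {
      "additionalProperties": {
        "enum": [
          "fulfilled",
          "not_fulfilled",
          "not_applicable"
        ],
        "type": "string"
      },
      "title": "Statuses",
      "type": "object"
    }
  },
  "required": [
    "study_id",
    "profile",
    "statuses"
  ],
  "title": "AssessmentDocument",
  "type": "object"
}
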