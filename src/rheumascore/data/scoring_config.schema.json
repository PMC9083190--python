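{
 "$defs": {
  "AnswerOption": {
   "additionalProperties": false,
   "description": "One selectable answer, with its per-disease integer weights.\n\nA weight absent from ``weights`` means the option contributes 0 points\nto that disease. One option may carry weights for several diseases at\nonce (one symptom can inform many diagnoses). Negative weights are\npermitted by the schema; the shipped default uses non-negative weights\nonly.",
   "properties": {
    "id": {
     "minLength": 1,
     "title": "Id",
     "type": "string"
    },
    "label": {
     "minLength": 1,
     "title": "Label",
     "type": "string"
    },
    "weights": {
     "additionalProperties": {
      "type": "integer"
     },
     "title": "Weights",
     "type": "object"
    }
   },
   "required": [
    "id",
    "label"
   ],
   "title": "AnswerOption",
   "type": "object"
  },
  "Disease": {
   "additionalProperties": false,
   "description": "A disease the instrument screens for.",
   "properties": {
    "id": {
     "minLength": 1,
     "title": "Id",
     "type": "string"
    },
    "name": {
     "minLength": 1,
     "title": "Name",
     "type": "string"
    }
   },
   "required": [
    "id",
    "name"
   ],
   "title": "Disease",
   "type": "object"
  },
  "DiseaseThresholds": {
   "additionalProperties": false,
   "description": "Per-disease triage cut-offs. A score >= threshold passes it.",
   "properties": {
    "disease_id": {
     "minLength": 1,
     "title": "Disease Id",
     "type": "string"
    },
    "threshold1": {
     "title": "Threshold1",
     "type": "integer"
    },
    "threshold2": {
     "title": "Threshold2",
     "type": "integer"
    }
   },
   "required": [
    "disease_id",
    "threshold1",
    "threshold2"
   ],
   "title": "DiseaseThresholds",
   "type": "object"
  },
  "Question": {
   "additionalProperties": false,
   "properties": {
    "id": {
     "minLength": 1,
     "title": "Id",
     "type": "string"
    },
    "text": {
     "minLength": 1,
     "title": "Text",
     "type": "string"
    },
    "kind": {
     "enum": [
      "single_choice",
      "multi_choice",
      "boolean"
     ],
     "title": "Kind",
     "type": "string"
    },
    "options": {
     "items": {
      "$ref": "#/$defs/AnswerOption"
     },
     "title": "Options",
     "type": "array"
    },
    "required": {
     "default": false,
     "title": "Required",
     "type": "boolean"
    }
   },
   "required": [
    "id",
    "text",
    "kind",
    "options"
   ],
   "title": "Question",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "properties": {
  "version": {
   "default": "1",
   "title": "Version",
   "type": "string"
  },
  "diseases": {
   "items": {
    "$ref": "#/$defs/Disease"
   },
   "title": "Diseases",
   "type": "array"
  },
  "questions": {
   "items": {
    "$ref": "#/$defs/Question"
   },
   "title": "Questions",
   "type": "array"
  },
  "thresholds": {
   "items": {
    "$ref": "#/$defs/DiseaseThresholds"
   },
   "title": "Thresholds",
   "type": "array"
  }
 },
 "required": [
  "diseases",
  "questions",
  "thresholds"
 ],
 "title": "ScoringConfig",
 "type": "object"
}
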