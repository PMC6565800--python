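{
 "$defs": {
  "ContrastReport": {
   "properties": {
    "parameter": {
     "title": "Parameter",
     "type": "string"
    },
    "muscle": {
     "title": "Muscle",
     "type": "string"
    },
    "group_a": {
     "title": "Group A",
     "type": "string"
    },
    "group_b": {
     "title": "Group B",
     "type": "string"
    },
    "n_a": {
     "title": "N A",
     "type": "integer"
    },
    "n_b": {
     "title": "N B",
     "type": "integer"
    },
    "test_used": {
     "title": "Test Used",
     "type": "string"
    },
    "statistic": {
     "title": "Statistic",
     "type": "number"
    },
    "p_value": {
     "title": "P Value",
     "type": "number"
    },
    "percent_change": {
     "title": "Percent Change",
     "type": "integer"
    },
    "significant": {
     "title": "Significant",
     "type": "boolean"
    }
   },
   "required": [
    "parameter",
    "muscle",
    "group_a",
    "group_b",
    "n_a",
    "n_b",
    "test_used",
    "statistic",
    "p_value",
    "percent_change",
    "significant"
   ],
   "title": "ContrastReport",
   "type": "object"
  },
  "ErrorEntry": {
   "properties": {
    "spectrum_file": {
     "title": "Spectrum File",
     "type": "string"
    },
    "error": {
     "title": "Error",
     "type": "string"
    }
   },
   "required": [
    "spectrum_file",
    "error"
   ],
   "title": "ErrorEntry",
   "type": "object"
  },
  "RecordingReport": {
   "properties": {
    "subject_id": {
     "title": "Subject Id",
     "type": "string"
    },
    "muscle": {
     "title": "Muscle",
     "type": "string"
    },
    "side": {
     "title": "Side",
     "type": "string"
    },
    "gender": {
     "title": "Gender",
     "type": "string"
    },
    "accepted": {
     "title": "Accepted",
     "type": "boolean"
    },
    "reasons": {
     "items": {
      "type": "string"
     },
     "title": "Reasons",
     "type": "array"
    },
    "cole": {
     "additionalProperties": {
      "type": "number"
     },
     "title": "Cole",
     "type": "object"
    },
    "derived": {
     "additionalProperties": {
      "type": "number"
     },
     "title": "Derived",
     "type": "object"
    },
    "zscores": {
     "additionalProperties": {
      "type": "number"
     },
     "title": "Zscores",
     "type": "object"
    }
   },
   "required": [
    "subject_id",
    "muscle",
    "side",
    "gender",
    "accepted",
    "reasons",
    "cole",
    "derived",
    "zscores"
   ],
   "title": "RecordingReport",
   "type": "object"
  }
 },
 "description": "Machine-readable result of one pipeline run.",
 "properties": {
  "n_recordings": {
   "title": "N Recordings",
   "type": "integer"
  },
  "n_accepted": {
   "title": "N Accepted",
   "type": "integer"
  },
  "recordings": {
   "items": {
    "$ref": "#/$defs/RecordingReport"
   },
   "title": "Recordings",
   "type": "array"
  },
  "gender_contrasts": {
   "items": {
    "$ref": "#/$defs/ContrastReport"
   },
   "title": "Gender Contrasts",
   "type": "array"
  },
  "age_contrasts": {
   "items": {
    "$ref": "#/$defs/ContrastReport"
   },
   "title": "Age Contrasts",
   "type": "array"
  },
  "errors": {
   "items": {
    "$ref": "#/$defs/ErrorEntry"
   },
   "title": "Errors",
   "type": "array"
  }
 },
 "required": [
  "n_recordings",
  "n_accepted",
  "recordings",
  "gender_contrasts",
  "age_contrasts",
  "errors"
 ],
 "title": "PipelineReport",
 "type": "object"
}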