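{
  "description": "Envelope common to every subcommand report.",
  "properties": {
    "tool": {
      "default": "cneqc",
      "title": "Tool",
      "type": "string"
    },
    "version": {
      "title": "Version",
      "type": "string"
    },
    "subcommand": {
      "title": "Subcommand",
      "type": "string"
    },
    "timestamp": {
      "title": "Timestamp",
      "type": "string"
    },
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "config_sha256": {
      "title": "Config Sha256",
      "type": "string"
    },
    "summary": {
      "additionalProperties": true,
      "title": "Summary",
      "type": "object"
    }
  },
  "required": [
    "version",
    "subcommand",
    "timestamp",
    "config_sha256"
  ],
  "title": "ReportEnvelope",
  "type": "object"
}
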