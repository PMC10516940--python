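{
  "$defs": {
    "RunConfig": {
      "additionalProperties": false,
      "description": "Flat key-value run configuration; unknown keys are rejected.",
      "properties": {
        "format_version": {
          "default": "1",
          "title": "Format Version",
          "type": "string"
        },
        "out_dir": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Out Dir"
        },
        "params": {
          "additionalProperties": {
            "anyOf": [
              {
                "type": "string"
              },
              {
                "type": "integer"
              },
              {
                "type": "number"
              },
              {
                "type": "boolean"
              }
            ]
          },
          "title": "Params",
          "type": "object"
        },
        "seed": {
          "default": 0,
          "title": "Seed",
          "type": "integer"
        },
        "subcommand": {
          "title": "Subcommand",
          "type": "string"
        }
      },
      "required": [
        "subcommand"
      ],
      "title": "RunConfig",
      "type": "object"
    }
  },
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "additionalProperties": false,
  "description": "Structured output of one tool invocation.",
  "properties": {
    "config": {
      "$ref": "#/$defs/RunConfig"
    },
    "created": {
      "title": "Created",
      "type": "string"
    },
    "curve_summary": {
      "anyOf": [
        {
          "additionalProperties": true,
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Curve Summary"
    },
    "enrichment": {
      "anyOf": [
        {
          "additionalProperties": true,
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Enrichment"
    },
    "outputs": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Outputs",
      "type": "object"
    },
    "purity_estimate": {
      "anyOf": [
        {
          "additionalProperties": true,
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Purity Estimate"
    },
    "sort_report": {
      "anyOf": [
        {
          "additionalProperties": true,
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Sort Report"
    },
    "tool_version": {
      "title": "Tool Version",
      "type": "string"
    }
  },
  "required": [
    "config",
    "tool_version",
    "created"
  ],
  "title": "iacsim run report",
  "type": "object"
}
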