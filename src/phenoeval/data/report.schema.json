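{
  "$defs": {
    "_AggregateModel": {
      "properties": {
        "average": {
          "title": "Average",
          "type": "number"
        },
        "min": {
          "title": "Min",
          "type": "number"
        },
        "max": {
          "title": "Max",
          "type": "number"
        }
      },
      "required": [
        "average",
        "min",
        "max"
      ],
      "title": "_AggregateModel",
      "type": "object"
    },
    "_ReportRowModel": {
      "properties": {
        "phenotype_name": {
          "title": "Phenotype Name",
          "type": "string"
        },
        "metrics": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Metrics",
          "type": "object"
        },
        "diagnostics": {
          "items": {
            "type": "string"
          },
          "title": "Diagnostics",
          "type": "array"
        }
      },
      "required": [
        "phenotype_name",
        "metrics"
      ],
      "title": "_ReportRowModel",
      "type": "object"
    }
  },
  "description": "Serialized form of a :class:`ReportDocument`; doubles as its JSON schema.",
  "properties": {
    "schema_version": {
      "default": 1,
      "title": "Schema Version",
      "type": "integer"
    },
    "rows": {
      "items": {
        "$ref": "#/$defs/_ReportRowModel"
      },
      "title": "Rows",
      "type": "array"
    },
    "aggregates": {
      "additionalProperties": {
        "$ref": "#/$defs/_AggregateModel"
      },
      "title": "Aggregates",
      "type": "object"
    }
  },
  "required": [
    "rows",
    "aggregates"
  ],
  "title": "ReportModel",
  "type": "object"
}
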