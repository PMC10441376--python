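{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "mriokit knowledge-base document",
  "description": "YAML/JSON document form of a mriokit KnowledgeBase, as read by load_kb() and written by save_kb(). Users may extend or override acquisition rules by editing this document and passing it via --kb; structural validity is enforced at load time by validate_kb().",
  "type": "object",
  "required": ["mriokit_kb", "terms"],
  "properties": {
    "mriokit_kb": {"const": 1, "description": "document format version"},
    "terms": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["iri", "label"],
        "properties": {
          "iri": {"type": "string", "pattern": "^(MRIO|OBI|IAO|UBERON|MRIOKIT):\\S+$"},
          "label": {"type": "string"},
          "definition": {"type": "string"},
          "parent_iri": {"type": "string"},
          "namespace": {"enum": ["MRIO", "OBI", "IAO", "UBERON", "PROVISIONAL"]},
          "synonyms": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "axioms": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["type_iri", "constraints"],
        "properties": {
          "type_iri": {"type": "string"},
          "provenance": {"enum": ["PAPER", "DEFAULT"]},
          "constraints": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["parameter", "kind"],
              "properties": {
                "parameter": {"type": "string"},
                "kind": {
                  "enum": [
                    "open_interval",
                    "half_open",
                    "equality",
                    "categorical_membership",
                    "presence"
                  ]
                },
                "low": {"type": "number"},
                "high": {"type": "number"},
                "low_inclusive": {"type": "boolean"},
                "high_inclusive": {"type": "boolean"},
                "value": {},
                "allowed_values": {"type": "array"},
                "tolerance": {"type": "number"}
              }
            }
          }
        }
      }
    },
    "analyses": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["iri", "label", "input_dnf"],
        "properties": {
          "iri": {"type": "string"},
          "label": {"type": "string"},
          "input_dnf": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "array",
              "minItems": 1,
              "items": {"type": "string"},
              "description": "one conjunct: all listed type CURIEs required"
            }
          },
          "outputs": {"type": "array", "items": {"type": "string"}},
          "software_family": {"type": "string"},
          "provenance": {"enum": ["PAPER", "DEFAULT"]}
        }
      }
    },
    "bridge": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["mrio_iri", "dicom_tag", "bids_key"],
        "properties": {
          "mrio_iri": {"type": "string"},
          "dicom_tag": {"type": "string", "pattern": "^[0-9A-Fa-f]{4},[0-9A-Fa-f]{4}$"},
          "bids_key": {"type": "string"},
          "unit_dicom": {"type": "string"},
          "unit_bids": {"type": "string"},
          "scale_dicom_to_bids": {"type": "number", "exclusiveMinimum": 0},
          "provenance": {"enum": ["PAPER", "DEFAULT"]}
        }
      }
    },
    "atlases": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["atlas_iri", "regions"],
        "properties": {
          "atlas_iri": {"type": "string"},
          "regions": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["region_label", "anatomy_xref"],
              "properties": {
                "region_label": {"type": "string"},
                "anatomy_xref": {"type": "string"}
              }
            }
          }
        }
      }
    }
  }
}
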