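{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "HDG catalog row",
  "description": "Schema for one row of the gene catalog TSV (hdg_catalog.tsv). cluster_id is empty exactly when subunit_role is standalone.",
  "type": "object",
  "properties": {
    "gene_symbol": {"type": "string", "minLength": 1},
    "ko_code": {"type": "string", "pattern": "^$|^K[0-9]{5}$"},
    "functional_group": {"enum": ["alkane", "MAH", "PAH", "various"]},
    "cluster_id": {"type": "string"},
    "subunit_role": {
      "enum": ["structural", "electron_transport_or_reductase", "standalone"]
    },
    "general_metabolism": {"enum": ["0", "1"]},
    "model_length_aa": {"type": "string", "pattern": "^[1-9][0-9]*$"},
    "provenance": {"enum": ["named", "curated"]}
  },
  "required": [
    "gene_symbol", "ko_code", "functional_group", "cluster_id",
    "subunit_role", "general_metabolism", "model_length_aa"
  ],
  "allOf": [
    {
      "if": {"properties": {"subunit_role": {"const": "standalone"}}},
      "then": {"properties": {"cluster_id": {"const": ""}}},
      "else": {"properties": {"cluster_id": {"minLength": 1}}}
    }
  ]
}
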