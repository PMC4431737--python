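{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "functree-tree-document",
  "title": "Functional Tree document",
  "description": "Nested-children JSON dialect for the five-layer Functional Tree. Layer order along any root-to-leaf path is root -> biological_category -> biological_process -> pathway -> module -> ko, except that a ko node may be a direct child of a pathway. 'hidden' is true exactly on the Undefined Biological Category node and its descendants.",
  "type": "object",
  "required": ["schema_version", "root"],
  "additionalProperties": false,
  "properties": {
    "schema_version": {"const": 1},
    "root": {"$ref": "#/definitions/node"}
  },
  "definitions": {
    "node": {
      "type": "object",
      "required": ["id", "name", "layer", "hidden", "children"],
      "additionalProperties": false,
      "properties": {
        "id": {"type": "string", "pattern": "^[^/]+$"},
        "name": {"type": "string"},
        "layer": {
          "enum": ["root", "biological_category", "biological_process",
                   "pathway", "module", "ko"]
        },
        "hidden": {"type": "boolean"},
        "children": {"type": "array", "items": {"$ref": "#/definitions/node"}}
      }
    }
  }
}
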