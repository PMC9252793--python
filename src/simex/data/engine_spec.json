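{
  "id": "simex",
  "version": "0.1.0",
  "name": "simex reference simulation engine",
  "model_formats": [
    "http://identifiers.org/combine.specifications/sbml",
    "http://purl.org/NET/mediatypes/text/x-boolnet"
  ],
  "frameworks": [
    "SBO:0000293",
    "SBO:0000295",
    "SBO:0000234"
  ],
  "algorithms": [
    {
      "kisao_id": "KISAO:0000030",
      "parameters": [
        {"kisao_id": "KISAO:0000483", "data_type": "float"}
      ],
      "supported_formats": ["http://identifiers.org/combine.specifications/sbml"]
    },
    {
      "kisao_id": "KISAO:0000032",
      "parameters": [
        {"kisao_id": "KISAO:0000483", "data_type": "float"},
        {"kisao_id": "KISAO:0000209", "data_type": "float"},
        {"kisao_id": "KISAO:0000211", "data_type": "float"}
      ],
      "supported_formats": ["http://identifiers.org/combine.specifications/sbml"]
    },
    {
      "kisao_id": "KISAO:0000029",
      "parameters": [
        {"kisao_id": "KISAO:0000488", "data_type": "integer"}
      ],
      "supported_formats": ["http://identifiers.org/combine.specifications/sbml"]
    },
    {
      "kisao_id": "KISAO:0000449",
      "parameters": [],
      "supported_formats": ["http://purl.org/NET/mediatypes/text/x-boolnet"]
    },
    {
      "kisao_id": "KISAO:0000450",
      "parameters": [
        {"kisao_id": "KISAO:0000488", "data_type": "integer"}
      ],
      "supported_formats": ["http://purl.org/NET/mediatypes/text/x-boolnet"]
    }
  ],
  "license": "MIT",
  "cli_available": true
}
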