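{
  "schema_version": 1,
  "reference_dairy_servings": 3.0,
  "plans": [
    {"name": "Model 1", "components": [{"ref": "composite:A", "servings": 3}]},
    {"name": "Model 2", "components": [{"ref": "composite:A", "servings": 2}, {"ref": "composite:B", "servings": 1}]},
    {"name": "Model 3", "components": [{"ref": "composite:A", "servings": 2}, {"ref": "composite:C", "servings": 1}]},
    {"name": "Model 4", "components": [{"ref": "composite:A", "servings": 2}, {"ref": "food:11111000", "servings": 1}]},
    {"name": "Model 5", "components": [{"ref": "composite:A", "servings": 2}, {"ref": "food:11112110", "servings": 1}]},
    {"name": "Model 6", "components": [{"ref": "composite:A", "servings": 2}, {"ref": "food:14410110", "servings": 1}]},
    {"name": "Model 7", "components": [{"ref": "composite:A", "servings": 2}, {"ref": "food:14410120", "servings": 1}]}
  ]
}
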