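{
  "composite_specs.json": "b3e739e82171719c2f6a33a6924d572fd0f1a937ddb58808b57ff3aa81231647",
  "dri.csv": "32696bef725678580fb97406f782d4b0bf53161013087a80d36cfabaade5eeb5",
  "model_tables.csv": "b8605352ca4dde207915dde69920c82ecdba6627c038d75d42abf510570eb58c",
  "panel.csv": "f1eb0f831fbddec691a38deb8c353d6dc4c34b85f713f1eee7e2579c4a2558b9",
  "plans.json": "33fdc13c4c7598ad2caa33fea2793db547c036b14a4c5cd6fd11ed0d390cd1f2",
  "synthetic_foods.csv": "c8c4f57aad81ccf17d051f10973d76f01e05009a664e2c5bbdcfc2b2dc050403",
  "table1_composites.csv": "4377480c15f3e0ef6d6679e68abb8445857c267ec440921b502179bdbe6adf02",
  "table4_goals.csv": "1befd5aed53d7ce6f9b918d3798db3486ba0dde975290fccda840bde244c46f1",
  "usda_pattern.csv": "00c168bd9f48957d72055c081fd795952c1b3b3a166326ab8084ee6c929e1dbb"
}
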