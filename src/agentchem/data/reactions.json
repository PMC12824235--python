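[
  "methane + 2 oxygen -> carbon dioxide + 2 water",
  "2 carbon monoxide + oxygen -> 2 carbon dioxide",
  "nitrogen + 3 hydrogen -> 2 ammonia",
  "hydrogen + chlorine -> 2 hydrogen chloride",
  "ethylene + hydrogen -> ethane",
  "carbon monoxide + water -> carbon dioxide + hydrogen",
  "ethanol + 3 oxygen -> 2 carbon dioxide + 3 water",
  "2 hydrogen + oxygen -> 2 water",
  "methane + water -> carbon monoxide + 3 hydrogen",
  "propene + hydrogen -> propane",
  "2 hydrogen peroxide -> 2 water + oxygen",
  "carbon monoxide + 2 hydrogen -> methanol",
  "acetylene + 2 hydrogen -> ethane",
  "formaldehyde + hydrogen -> methanol",
  "methanol + carbon monoxide -> acetic acid"
]
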