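{
  "description": "Curated RIP2 CARD filament interface annotations. Death-domain filaments bury three conserved asymmetric interfaces (type I, II, III), each pairing an 'a' surface on one subunit with a 'b' surface on a neighbour. Residue numbers follow author numbering within the modelled range 433-518 (C-terminal residues up to 514 appear in interface lists).",
  "modelled_range": [433, 518],
  "annotations": [
    {
      "type": "I",
      "surface_a": [441, 444, 445, 448, 489, 492, 495],
      "surface_b": [457, 461, 467, 471],
      "pairs": [[444, 461], [448, 457]]
    },
    {
      "type": "II",
      "surface_a": [470, 497],
      "surface_b": [450, 452, 453, 455, 458, 512, 514],
      "pairs": [[470, 455], [497, 450], [497, 452], [497, 514], [512, 458]]
    },
    {
      "type": "III",
      "surface_a": [472, 475, 481, 482],
      "surface_b": [476, 483, 484, 488],
      "pairs": [[472, 488], [472, 483], [475, 483], [475, 488]]
    }
  ]
}
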