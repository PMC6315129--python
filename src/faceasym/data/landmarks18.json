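{
  "description": "Default 18-landmark facial schema: 6 midline landmarks and 6 bilateral pairs using standard anthropometric names. In the aligned frame the midsagittal plane is x = 0, +x is the subject's left, +y superior, +z anterior.",
  "midline": [
    "nasion",
    "pronasale",
    "subnasale",
    "labiale_superius",
    "labiale_inferius",
    "pogonion"
  ],
  "pairs": [
    ["endocanthion_l", "endocanthion_r"],
    ["exocanthion_l", "exocanthion_r"],
    ["alare_l", "alare_r"],
    ["cheilion_l", "cheilion_r"],
    ["crista_philtri_l", "crista_philtri_r"],
    ["gonion_l", "gonion_r"]
  ]
}
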