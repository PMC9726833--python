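{
  "version": 1,
  "activity_period": [
    "Diurnal",
    "Diurnal cathemeral",
    "Nocturnal cathemeral",
    "Crepuscular",
    "Near obligate nocturnal",
    "Obligate nocturnal"
  ],
  "habitat_type": ["Open", "Semi-open", "Closed"],
  "diet": [
    "Invertivore",
    "Vertivore",
    "Aquatic invertivore",
    "Aquatic vertivore",
    "Aquatic herbivore",
    "Frugivore",
    "Granivore",
    "Nectarivore",
    "Herbivore",
    "Omnivore"
  ],
  "foraging_method": [
    "Skimming",
    "Dabbling",
    "Dipping",
    "Diving",
    "Gleaning",
    "Hawking",
    "Sallying",
    "Lunging",
    "Scratching",
    "Plunge diving",
    "Probing",
    "Scanning"
  ],
  "foraging_height": ["Low", "Various", "High"],
  "reference_levels": {
    "activity_period": "Diurnal",
    "habitat_type": "Open",
    "foraging_method": "Dabbling",
    "foraging_height": "Low",
    "diet": "Aquatic herbivore"
  },
  "bristle_regions": [
    "upper_rictal",
    "lorial",
    "lower_rictal",
    "narial",
    "interramal"
  ],
  "shape_categories": ["Absent", "Base", "Branched", "Unbranched"]
}
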