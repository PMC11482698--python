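{
 "units": {
  "Sa": {
   "kind": "surrounding_area",
   "display_name": "Saharan region"
  },
  "O": {
   "kind": "surrounding_area",
   "display_name": "Oriental realm"
  },
  "W": {
   "kind": "surrounding_area",
   "display_name": "Western Asian mountains transition zone"
  },
  "Tu": {
   "kind": "surrounding_area",
   "display_name": "Turanian region"
  },
  "Ar": {
   "kind": "surrounding_area",
   "display_name": "Arabian region"
  },
  "Ir": {
   "kind": "surrounding_area",
   "display_name": "Iranian region"
  },
  "Ce": {
   "kind": "iran_region",
   "display_name": "Central Plateau",
   "area_fraction": 0.3319
  },
  "Ca": {
   "kind": "iran_region",
   "display_name": "Caspian",
   "area_fraction": 0.0058
  },
  "A": {
   "kind": "iran_region",
   "display_name": "Alborz Mountains",
   "area_fraction": 0.0774
  },
  "M": {
   "kind": "iran_region",
   "display_name": "Moghan Steppe",
   "area_fraction": 0.0165
  },
  "R": {
   "kind": "iran_region",
   "display_name": "Reza'iyeh (Urmia) Basin",
   "area_fraction": 0.0433
  },
  "Z": {
   "kind": "iran_region",
   "display_name": "Zagros Mountains",
   "area_fraction": 0.208
  },
  "WZ": {
   "kind": "iran_region",
   "display_name": "Western Foothills of the Zagros Mountains",
   "area_fraction": 0.0214
  },
  "Kh": {
   "kind": "iran_region",
   "display_name": "Khuzestan Plain and the Persian Gulf Coast",
   "area_fraction": 0.0821
  },
  "T": {
   "kind": "iran_region",
   "display_name": "Turkmen Steppe",
   "area_fraction": 0.0077
  },
  "K": {
   "kind": "iran_region",
   "display_name": "Kopet-Dagh",
   "area_fraction": 0.0669
  },
  "S": {
   "kind": "iran_region",
   "display_name": "Sistan Basin",
   "area_fraction": 0.0164
  },
  "B": {
   "kind": "iran_region",
   "display_name": "Iranian Baluchistan and the Makran Coast",
   "area_fraction": 0.1215
  },
  "I": {
   "kind": "iran_region",
   "display_name": "Islands of the Persian Gulf",
   "area_fraction": 0.0012
  }
 },
 "taxa": {
  "provisional": [
   "Eirenis cf. persicus",
   "Platyceps cf. r. rhodorachis"
  ],
  "endemic": [
   "Xerotyphlops luristanicus",
   "Eryx sistanensis",
   "Eirenis kermanensis",
   "Eirenis rafsanjanicus",
   "Eirenis rechingeri",
   "Eirenis yassujicus",
   "Persiophis fahimii",
   "Spalerosophis microlepis",
   "Bungarus persicus",
   "Macrovipera razii",
   "Montivipera kuhrangica",
   "Montivipera latifii"
  ],
  "notes": "provisional: open-nomenclature (cf.) records of species listed separately; excluded from counted totals. endemic: illustrative curation of Iran-endemic taxa; metadata only."
 }
}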