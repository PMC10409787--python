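{
  "thiamine": {
    "stages": [
      {"name": "thiazole_production", "kos": ["K03149", "K03146"]},
      {"name": "pyrimidine_synthesis", "kos": ["K03147"]},
      {"name": "moiety_linking", "kos": ["K00788", "K14153"]},
      {"name": "kinases", "kos": ["K00946", "K00941", "K00949"]}
    ],
    "near_complete_exempt_kos": ["K03147"]
  },
  "biotin": {
    "stages": [
      {"name": "pimeloyl_acp_synthesis", "kos": ["K02169", "K02170", "K16593"]},
      {"name": "kapa_synthesis", "kos": ["K00652"]},
      {"name": "dapa_synthesis", "kos": ["K00833", "K19563"]},
      {"name": "dethiobiotin_synthesis", "kos": ["K01935"]},
      {"name": "biotin_synthase", "kos": ["K01012"]}
    ],
    "near_complete_exempt_kos": []
  },
  "tetrahydrofolate": {
    "stages": [
      {"name": "gtp_cyclohydrolase", "kos": ["K01495", "K09007"]},
      {"name": "aminodeoxychorismate", "kos": ["K01665", "K13950"]},
      {"name": "dihydropteroate_synthase", "kos": ["K00796"]},
      {"name": "dihydrofolate_synthase", "kos": ["K11754", "K01930"]},
      {"name": "dihydrofolate_reductase", "kos": ["K00287", "K13938"]}
    ],
    "near_complete_exempt_kos": []
  },
  "riboflavin": {
    "stages": [
      {"name": "gtp_cyclohydrolase_ii", "kos": ["K01497", "K14652"]},
      {"name": "deaminase_reductase", "kos": ["K11752"]},
      {"name": "lumazine_synthase", "kos": ["K00794"]},
      {"name": "riboflavin_synthase", "kos": ["K00793"]}
    ],
    "near_complete_exempt_kos": []
  },
  "NAD": {
    "stages": [
      {"name": "aspartate_oxidase", "kos": ["K00278"]},
      {"name": "quinolinate_synthase", "kos": ["K03517"]},
      {"name": "quinolinate_phosphoribosyltransferase", "kos": ["K00767"]},
      {"name": "namn_adenylyltransferase", "kos": ["K00969", "K06210"]},
      {"name": "nad_synthetase", "kos": ["K01916", "K01950"]}
    ],
    "near_complete_exempt_kos": []
  },
  "pantothenate": {
    "stages": [
      {"name": "ketopantoate_hydroxymethyltransferase", "kos": ["K00606"]},
      {"name": "ketopantoate_reductase", "kos": ["K00077", "K00053"]},
      {"name": "aspartate_decarboxylase", "kos": ["K01579", "K13524"]},
      {"name": "pantothenate_synthetase", "kos": ["K01918"]}
    ],
    "near_complete_exempt_kos": []
  }
}
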