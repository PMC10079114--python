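{
  "nationalism": {
    "items": ["nat_1", "nat_2", "nat_3", "nat_4", "nat_5", "nat_6", "nat_7"],
    "range": [1, 7],
    "reverse": []
  },
  "nationalism_ext": {
    "items": ["nat_1", "nat_2", "nat_3", "nat_4", "nat_5", "nat_6", "nat_7", "nat_8"],
    "range": [1, 7],
    "reverse": []
  },
  "sid_national": {
    "items": ["sid_nat_1", "sid_nat_2", "sid_nat_3", "sid_nat_4"],
    "range": [1, 7],
    "reverse": []
  },
  "sid_religious": {
    "items": ["sid_rel_1", "sid_rel_2", "sid_rel_3", "sid_rel_4"],
    "range": [1, 7],
    "reverse": []
  },
  "fusion_national": {
    "items": ["fus_nat_1", "fus_nat_2", "fus_nat_3", "fus_nat_4", "fus_nat_5", "fus_nat_6", "fus_nat_7"],
    "range": [1, 7],
    "reverse": []
  },
  "fusion_religious": {
    "items": ["fus_rel_1", "fus_rel_2", "fus_rel_3", "fus_rel_4", "fus_rel_5", "fus_rel_6", "fus_rel_7"],
    "range": [1, 7],
    "reverse": []
  },
  "sbs_original": {
    "items": ["sbs_1", "sbs_2", "sbs_3", "sbs_4", "sbs_5", "sbs_6", "sbs_7", "sbs_8", "sbs_9", "sbs_10"],
    "range": [1, 9],
    "reverse": []
  },
  "sbs_extended": {
    "items": ["sbs_1", "sbs_2", "sbs_3", "sbs_4", "sbs_5", "sbs_6", "sbs_7", "sbs_8", "sbs_9", "sbs_10", "sbs_karma", "sbs_universal_force"],
    "range": [1, 9],
    "reverse": []
  },
  "threat_social": {
    "items": ["thr_social_1", "thr_social_2", "thr_social_3"],
    "range": [1, 5],
    "reverse": []
  },
  "threat_predation": {
    "items": ["thr_predation_1", "thr_predation_2", "thr_predation_3"],
    "range": [1, 5],
    "reverse": []
  },
  "threat_contagion": {
    "items": ["thr_contagion_1", "thr_contagion_2", "thr_contagion_3"],
    "range": [1, 5],
    "reverse": []
  },
  "threat_financial": {
    "items": ["thr_financial_1", "thr_financial_2", "thr_financial_3"],
    "range": [1, 5],
    "reverse": []
  },
  "threat_natural": {
    "items": ["thr_natural_1", "thr_natural_2", "thr_natural_3"],
    "range": [1, 5],
    "reverse": []
  },
  "big5_openness": {
    "items": ["b5_1", "b5_6"],
    "range": [1, 5],
    "reverse": []
  },
  "big5_conscientiousness": {
    "items": ["b5_2", "b5_7"],
    "range": [1, 5],
    "reverse": []
  },
  "big5_extraversion": {
    "items": ["b5_3", "b5_8"],
    "range": [1, 5],
    "reverse": []
  },
  "big5_agreeableness": {
    "items": ["b5_4", "b5_9"],
    "range": [1, 5],
    "reverse": []
  },
  "big5_neuroticism": {
    "items": ["b5_5", "b5_10"],
    "range": [1, 5],
    "reverse": []
  }
}
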