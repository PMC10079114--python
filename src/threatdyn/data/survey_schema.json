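{
  "required": [
    "gender", "age", "religious_identity", "rel_attendance",
    "threat_social", "threat_predation", "threat_contagion",
    "threat_financial", "threat_natural",
    "nationalism_full", "sid_national", "sid_religious",
    "fusion_national", "fusion_religious", "sbs_extended",
    "politics_social", "politics_economic",
    "wvs_undesirable_immigrants",
    "big5_openness", "big5_conscientiousness", "big5_extraversion",
    "big5_agreeableness", "big5_neuroticism"
  ],
  "columns": [
    "respondent_id", "gender", "age", "religious_identity", "rel_attendance",
    "threat_social", "threat_predation", "threat_contagion", "threat_financial",
    "threat_natural", "threat_overall", "nationalism", "nationalism_full",
    "sid_national", "sid_religious", "fusion_national", "fusion_religious",
    "sbs_original", "sbs_extended", "big5_openness", "big5_conscientiousness",
    "big5_extraversion", "big5_agreeableness", "big5_neuroticism",
    "politics_social", "politics_economic", "covid_way_of_life",
    "social_media_use", "tv_media_use", "wvs_undesirable_immigrants",
    "covid_status", "brexit_vote"
  ],
  "categories": {
    "gender": ["man", "woman", "other"],
    "religious_identity": [
      "Agnostic", "Atheist", "Buddhist", "Catholic",
      "Church of England/Anglican", "Evangelical/Pentecostal/Charismatic",
      "Hindu", "Humanist", "Jewish", "Muslim", "None", "Other",
      "Protestant (misc.)", "Spiritual but not religious"
    ],
    "covid_status": [
      "tested_negative", "symptoms_untested", "currently_positive",
      "recovered", "none"
    ],
    "brexit_vote": ["leave", "remain"]
  },
  "ranges": {
    "age": [18, null],
    "rel_attendance": [0, 9],
    "threat_social": [1, 5], "threat_predation": [1, 5],
    "threat_contagion": [1, 5], "threat_financial": [1, 5],
    "threat_natural": [1, 5],
    "nationalism": [1, 7], "nationalism_full": [1, 7],
    "sid_national": [1, 7], "sid_religious": [1, 7],
    "fusion_national": [1, 7], "fusion_religious": [1, 7],
    "sbs_original": [1, 9], "sbs_extended": [1, 9],
    "big5_openness": [1, 5], "big5_conscientiousness": [1, 5],
    "big5_extraversion": [1, 5], "big5_agreeableness": [1, 5],
    "big5_neuroticism": [1, 5],
    "politics_social": [0, 10], "politics_economic": [0, 10],
    "covid_way_of_life": [1, 7],
    "social_media_use": [1, 5], "tv_media_use": [1, 4],
    "wvs_undesirable_immigrants": [0, 1]
  }
}
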