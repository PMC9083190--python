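{
 "negative": {
  "joint_pain": {
   "yes": 0.8,
   "no": 0.2
  },
  "joint_swelling": {
   "yes": 0.45,
   "no": 0.55
  },
  "morning_stiffness": {
   "none": 0.35,
   "short": 0.4,
   "medium": 0.18,
   "long": 0.07
  },
  "stiffness_improves_activity": {
   "yes": 0.25,
   "no": 0.75
  },
  "night_back_pain": {
   "yes": 0.12,
   "no": 0.88
  },
  "back_pain_onset": {
   "before_40": 0.08,
   "after_40": 0.4
  },
  "symmetric_small_joints": {
   "yes": 0.12,
   "no": 0.88
  },
  "photosensitive_rash": {
   "yes": 0.03,
   "no": 0.97
  },
  "mouth_ulcers": {
   "yes": 0.08,
   "no": 0.92
  },
  "dry_eyes_mouth": {
   "yes": 0.12,
   "no": 0.88
  },
  "raynaud": {
   "none": 0.85,
   "mild": 0.12,
   "severe": 0.03
  },
  "skin_thickening": {
   "yes": 0.02,
   "no": 0.98
  },
  "swallowing_difficulty": {
   "yes": 0.05,
   "no": 0.95
  },
  "proximal_muscle_weakness": {
   "none": 0.9,
   "mild": 0.08,
   "marked": 0.02
  },
  "muscle_pain": {
   "yes": 0.3,
   "no": 0.7
  },
  "fatigue": {
   "none": 0.35,
   "some": 0.45,
   "severe": 0.2
  },
  "unexplained_fever": {
   "yes": 0.05,
   "no": 0.95
  },
  "family_history": {
   "fam_ra": 0.1,
   "fam_psoriasis": 0.08,
   "fam_sle": 0.03,
   "fam_other": 0.15
  },
  "smoking": {
   "never": 0.5,
   "former": 0.3,
   "current": 0.2
  },
  "heel_tendon_pain": {
   "yes": 0.15,
   "no": 0.85
  },
  "psoriasis": {
   "yes": 0.07,
   "no": 0.93
  }
 },
 "positive": {
  "joint_pain": {
   "yes": 0.92,
   "no": 0.08
  },
  "joint_swelling": {
   "yes": 0.8,
   "no": 0.2
  },
  "morning_stiffness": {
   "none": 0.08,
   "short": 0.17,
   "medium": 0.35,
   "long": 0.4
  },
  "stiffness_improves_activity": {
   "yes": 0.6,
   "no": 0.4
  },
  "night_back_pain": {
   "yes": 0.38,
   "no": 0.62
  },
  "back_pain_onset": {
   "before_40": 0.32,
   "after_40": 0.28
  },
  "symmetric_small_joints": {
   "yes": 0.55,
   "no": 0.45
  },
  "photosensitive_rash": {
   "yes": 0.2,
   "no": 0.8
  },
  "mouth_ulcers": {
   "yes": 0.28,
   "no": 0.72
  },
  "dry_eyes_mouth": {
   "yes": 0.32,
   "no": 0.68
  },
  "raynaud": {
   "none": 0.55,
   "mild": 0.28,
   "severe": 0.17
  },
  "skin_thickening": {
   "yes": 0.14,
   "no": 0.86
  },
  "swallowing_difficulty": {
   "yes": 0.16,
   "no": 0.84
  },
  "proximal_muscle_weakness": {
   "none": 0.65,
   "mild": 0.23,
   "marked": 0.12
  },
  "muscle_pain": {
   "yes": 0.42,
   "no": 0.58
  },
  "fatigue": {
   "none": 0.15,
   "some": 0.45,
   "severe": 0.4
  },
  "unexplained_fever": {
   "yes": 0.22,
   "no": 0.78
  },
  "family_history": {
   "fam_ra": 0.28,
   "fam_psoriasis": 0.16,
   "fam_sle": 0.08,
   "fam_other": 0.22
  },
  "smoking": {
   "never": 0.45,
   "former": 0.27,
   "current": 0.28
  },
  "heel_tendon_pain": {
   "yes": 0.32,
   "no": 0.68
  },
  "psoriasis": {
   "yes": 0.16,
   "no": 0.84
  }
 }
}
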