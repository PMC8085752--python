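[
  {
    "feature": "asthma_relievers_filled_12m",
    "interval": [89, null],
    "interventions": [
      "Tailor prescribed medications; suggest the patient maximize adherence to asthma control medications or improve avoidance of asthma triggers."
    ]
  },
  {
    "feature": "nebulizer_medication_orders_12m",
    "interval": [25, null],
    "interventions": [
      "Tailor prescribed medications; suggest the patient maximize adherence to asthma control medications or improve avoidance of asthma triggers."
    ]
  },
  {
    "feature": "major_asthma_visits_12m",
    "interval": [16, null],
    "interventions": [
      "Adopt control strategies for the patient to avoid needing emergency care."
    ]
  },
  {
    "feature": "primary_asthma_diagnoses_12m",
    "interval": [8, 10],
    "interventions": [
      "Offer the patient suggestions on how to improve asthma control."
    ]
  },
  {
    "feature": "no_shows_12m",
    "interval": [6, null],
    "interventions": [
      "Give the patient social resources to handle socioeconomic challenges to keep appointments."
    ]
  },
  {
    "feature": "ed_visits_12m",
    "interval": [8, null],
    "interventions": [
      "Adopt control strategies for the patient to avoid needing emergency care."
    ]
  },
  {
    "feature": "saba_medication_orders_12m",
    "interval": [28, null],
    "interventions": [
      "Tailor prescribed medications; suggest the patient maximize adherence to asthma control medications or improve avoidance of asthma triggers."
    ]
  },
  {
    "feature": "race",
    "value": "black_or_african_american",
    "interventions": []
  },
  {
    "feature": "highest_exacerbation_severity_12m",
    "value": "status_asthmaticus",
    "interventions": [
      "Offer the patient suggestions on how to improve asthma control."
    ]
  },
  {
    "feature": "same_day_appointment_visits_12m",
    "interval": [11, 18],
    "interventions": [
      "Improve support offered to the patient between visits to enhance medication adherence, address asthma triggers, and maximize the value of each visit."
    ]
  },
  {
    "feature": "last_visit_admission_type_12m",
    "value": "nonelective",
    "interventions": [
      "Adopt control strategies for the patient to avoid needing emergency care."
    ]
  }
]
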