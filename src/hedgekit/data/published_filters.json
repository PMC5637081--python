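{
  "reference_set": {
    "initial_retrieval": 3095,
    "screened": 2102,
    "relevant": 431,
    "irrelevant": 1671
  },
  "filters": [
    {
      "name": "paramedic_sensitivity",
      "syntax": "ovid",
      "text": "Ambulances.sh OR Emergency Medical Technicians.sh OR Air Ambulances.sh OR emergency medical services.sh OR paramedic*.tw OR ems.tw OR emt.tw OR prehospital.tw OR pre-hospital.tw OR first responder*.tw OR emergency medical technicians.tw OR emergency services.tw OR Ambulance*.tw OR HEMS.tw OR field triage.tw OR out-of-hospital.tw",
      "reported_performance": {
        "sensitivity": 0.984,
        "specificity": 0.743,
        "nnr": 2.00
      }
    },
    {
      "name": "paramedic_specificity",
      "syntax": "ovid",
      "text": "Ambulances.sh OR Emergency Medical Technicians.sh OR Air Ambulances.sh OR paramedic*.tw OR ems.tw OR emt.tw OR prehospital.tw OR pre-hospital.tw OR first responder*.tw OR emergency medical technicians.tw OR emergency services.tw OR Ambulance*.tw OR HEMS.tw OR field triage.tw",
      "reported_performance": {
        "sensitivity": 0.947,
        "specificity": 0.883,
        "nnr": 1.48
      }
    },
    {
      "name": "prehospital",
      "syntax": "ovid",
      "text": null,
      "reported_performance": {
        "sensitivity": 0.974,
        "specificity": 0.654,
        "nnr": 2.44
      }
    }
  ]
}
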