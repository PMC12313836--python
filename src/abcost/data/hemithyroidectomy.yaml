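# Hemithyroidectomy with isthmectomy: removal of one thyroid lobe plus the
# isthmus.  The published comparative summary prints a personnel cost of
# 184.65 and a follow-up subtotal of 49.79; both are documented errata — the
# staff-table total (184.75) and the frequency-weighted course mixture
# (122.38) are what the published grand total 4,211.92 actually requires.
name: hemithyroidectomy
prehosp_items:
  - {label: Specialist consultation, quantity: "1.09", weighted_cost_override: "22.54"}
  - {label: Complete blood count (CBC), quantity: "1.00", weighted_cost_override: "3.17"}
  - {label: Prothrombin time (PT), quantity: "1.00", weighted_cost_override: "2.85"}
  - {label: Partial thromboplastin time (PTT), quantity: "1.00", weighted_cost_override: "2.85"}
  - {label: Fibrinogen, quantity: "1.00", weighted_cost_override: "2.67"}
  - {label: Electrocardiogram (ECG), quantity: "1.00", weighted_cost_override: "11.62"}
  - {label: Cardiology consultation, quantity: "1.00", weighted_cost_override: "20.66"}
  - {label: Otolaryngology consultation, quantity: "0.90", weighted_cost_override: "18.59"}
  - {label: Laryngoscopy, quantity: "0.90", weighted_cost_override: "24.40"}
  - {label: Neck ultrasound, quantity: "1.00", weighted_cost_override: "28.41"}
  - {label: Anesthesiology consultation, quantity: "1.00", weighted_cost_override: "20.66"}
  - {label: Thyroid fine-needle aspiration, quantity: "0.90", weighted_cost_override: "77.49"}
  - {label: Thyroid cytology exam, quantity: "0.90", weighted_cost_override: "30.40"}
  - {label: Chest X-ray, quantity: "1.00", weighted_cost_override: "15.49"}
drug_lines:
  - {category: anesthetics, drug: Midazolam, dose_mg: "1.50", cost: "0.20"}
  - {category: anesthetics, drug: Propofol, dose_mg: "175.00", cost: "2.58"}
  - {category: anesthetics, drug: Rocuronium, dose_mg: "52.50", cost: "3.47"}
  - {category: opioids, drug: Fentanyl, dose_mg: "0.21", cost: "0.62"}
  - {category: opioids, drug: Remifentanil, dose_mg: "3.94", cost: "11.97"}
  - {category: antibiotics, drug: Cefazolin, dose_mg: "2000.00", cost: "3.24"}
  - {category: corticosteroids, drug: Cortisone, dose_mg: "4.00", cost: "0.07"}
  - {category: corticosteroids, drug: Betamethasone, dose_mg: "4.00", cost: "0.77"}
  - {category: other, drug: Paracetamol, dose_mg: "1000.00", cost: "0.37"}
  - {category: other, drug: Sodium chloride, dose_mg: "1000.00", cost: "0.18"}
drug_policies:
  - {category: anesthetics, aggregation: printed_override, override_cost: "1.56"}
  - {category: opioids, aggregation: mean_of_alternatives}
  - {category: antibiotics, aggregation: mean_of_alternatives}
  - {category: corticosteroids, aggregation: mean_of_alternatives}
  - {category: other, aggregation: sum_of_lines}
material_items:
  - {label: Big clamp, quantity: "3.00", weighted_cost_override: "75.10"}
  - {label: Electrosurgical knife, quantity: "1.00", weighted_cost_override: "14.34"}
  - {label: Suture thread, quantity: "3.00", weighted_cost_override: "18.00"}
  - {label: Gauze, quantity: "13.00", weighted_cost_override: "1.28"}
  - {label: Surgical drape, quantity: "3.25", weighted_cost_override: "7.01"}
  - {label: Surgical swab, quantity: "3.25", weighted_cost_override: "7.15"}
  - {label: Sterile material pack, quantity: "1.00", weighted_cost_override: "24.52"}
  - {label: Jackson-Pratt drain, quantity: "0.83", weighted_cost_override: "2.56"}
staff_lines:
  - {role: Physician, headcount: "2.14", cost: "82.46"}
  - {role: Nurse, headcount: "1.14", cost: "20.35"}
  - {role: Anesthetist, headcount: "1.00", cost: "38.48"}
  - {role: Healthcare assistant, headcount: "0.67", cost: "25.65"}
  - {role: Surgical instrument technician, headcount: "1.00", cost: "17.81"}
facility:
  or_minutes: "66.43"
  or_cost: "1356.98"
  stay_days: "2.00"
  stay_cost: "1348.00"
  stay_rate_per_day: "674.00"
followup_courses:
  - name: standard
    frequency: "0.93"
    printed_total: "113.26"
    items:
      - {label: Specialist consultation, quantity: "1.50", weighted_cost_override: "30.99"}
      - {label: Complete blood count (CBC), quantity: "0.25", weighted_cost_override: "0.79"}
      - {label: Calcium test, quantity: "2.00", weighted_cost_override: "2.26"}
      - {label: Thyrotropin (TSH), quantity: "2.00", weighted_cost_override: "10.92"}
      - {label: Free thyroxine (FT4), quantity: "2.00", weighted_cost_override: "12.73"}
      - {label: Histological exam, quantity: "1.00", weighted_cost_override: "27.17"}
      - {label: Neck ultrasound, quantity: "1.00", weighted_cost_override: "28.41"}
  - name: acute_complications
    frequency: "0.035"
    printed_total: "227.91"
    items:
      - {label: Specialist consultation (endocrinology/otorhinolaryngology), quantity: "2.40", weighted_cost_override: "49.58"}
      - {label: Surgical consultation, quantity: "1.80", weighted_cost_override: "37.19"}
      - {label: Calcium test, quantity: "2.00", weighted_cost_override: "2.26"}
      - {label: Calcium infusion, quantity: "0.50", weighted_cost_override: "1.78"}
      - {label: Complete blood count (CBC), quantity: "1.17", weighted_cost_override: "3.17"}
      - {label: Thyrotropin (TSH), quantity: "1.00", weighted_cost_override: "5.46"}
      - {label: Neck ultrasound, quantity: "1.60", weighted_cost_override: "45.46"}
      - {label: Histological exam, quantity: "1.00", weighted_cost_override: "27.17"}
      - {label: Video-laryngoscopy, quantity: "1.00", weighted_cost_override: "27.11"}
      - {label: Cost of reoperation, quantity: "0.01", weighted_cost_override: "30.75"}
  - name: chronic_complications
    frequency: "0.035"
    printed_total: "259.13"
    items:
      - {label: Endocrinology consultation, quantity: "2.80", weighted_cost_override: "57.85"}
      - {label: Surgical consultation, quantity: "1.60", weighted_cost_override: "33.06"}
      - {label: Speech therapy, quantity: "7.50", weighted_cost_override: "110.42"}
      - {label: Calcium test, quantity: "1.00", weighted_cost_override: "1.13"}
      - {label: Thyrotropin (TSH), quantity: "2.00", weighted_cost_override: "10.92"}
      - {label: Histological exam, quantity: "1.00", weighted_cost_override: "27.17"}
      - {label: Neck ultrasound, quantity: "1.20", weighted_cost_override: "18.59"}
indirect:
  hosp_days: "2.00"
  convalescence_days: "8.50"
  hours_lost_per_day: "5"
  hourly_wage: "14.05"
  caregiver_share: "0.025"
  printed_patient_loss: "737.53"
  printed_caregiver_loss: "18.44"
retreatment_rate: "0"
printed_phase_totals:
  prehospitalization: "281.80"
  drugs: "12.08"
  personnel: "184.75"
summary_reference:
  prehospitalization: "281.80"
  drugs: "12.08"
  materials: "149.97"
  personnel: "184.65"           # erratum: staff table totals 184.75
  operating_room: "1356.98"
  hospital_stay: "1348.00"
  procedure_subtotal: "3051.77"
  followup_weighted.standard: "105.34"
  followup_weighted.acute_complications: "7.98"
  followup_weighted.chronic_complications: "9.07"
  followup_subtotal: "49.79"    # erratum: the weighted mixture is 122.38
  productivity: "755.97"
  grand_total.societal: "4211.92"
  grand_total.opportunity_cost_societal: "4027.17"
  materials_table_total: "2854.95"
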