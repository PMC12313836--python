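# Total thyroidectomy: inpatient surgery under general anesthesia.
# Cost columns are per-patient weighted values, stored as
# weighted_cost_override with the mean quantity kept as documentation.
name: total_thyroidectomy
prehosp_items:
  - {label: Specialist consultation, quantity: "1.09", weighted_cost_override: "22.54"}
  - {label: CBC, quantity: "1.00", weighted_cost_override: "3.17"}
  - {label: PT, quantity: "1.00", weighted_cost_override: "2.85"}
  - {label: PTT, quantity: "1.00", weighted_cost_override: "2.85"}
  - {label: Fibrinogen, quantity: "1.00", weighted_cost_override: "2.67"}
  - {label: ECG, quantity: "1.00", weighted_cost_override: "11.62"}
  - {label: Cardiology consultation, quantity: "1.00", weighted_cost_override: "20.66"}
  - {label: Otolaryngology consultation, quantity: "0.90", weighted_cost_override: "18.59"}
  - {label: Laryngoscopy, quantity: "0.90", weighted_cost_override: "24.40"}
  - {label: Neck ultrasound, quantity: "1.00", weighted_cost_override: "28.41"}
  - {label: Anesthesiology consultation, quantity: "1.00", weighted_cost_override: "20.66"}
  - {label: Thyroid fine-needle aspiration, quantity: "0.90", weighted_cost_override: "77.49"}
  - {label: Thyroid cytology exam, quantity: "0.90", weighted_cost_override: "30.40"}
  - {label: Chest X-ray, quantity: "1.00", weighted_cost_override: "15.49"}
drug_lines:
  - {category: anesthetics, drug: Midazolam, dose_mg: "0.75", cost: "0.10"}
  - {category: anesthetics, drug: Propofol, dose_mg: "175.00", cost: "2.58"}
  - {category: anesthetics, drug: Rocuronium, dose_mg: "52.50", cost: "3.47"}
  - {category: opioids, drug: Fentanyl, dose_mg: "0.21", cost: "0.62"}
  - {category: opioids, drug: Remifentanil, dose_mg: "3.94", cost: "11.97"}
  - {category: antibiotics, drug: Ceftriaxone, dose_mg: "1000.00", cost: "4.50"}
  - {category: antibiotics, drug: Cefazolin, dose_mg: "556.25", cost: "0.90"}
  - {category: corticosteroids, drug: Cortisone, dose_mg: "2.00", cost: "0.04"}
  - {category: corticosteroids, drug: Betamethasone, dose_mg: "4.00", cost: "0.77"}
  - {category: other, drug: Paracetamol, dose_mg: "1000.00", cost: "0.37"}
  - {category: other, drug: Sodium chloride, dose_mg: "1000.00", cost: "0.18"}
drug_policies:
  # the published anesthetics category cost (1.54) matches neither the sum
  # (6.15) nor the mean (2.05) of its lines; the usage weighting is unstated
  - {category: anesthetics, aggregation: printed_override, override_cost: "1.54"}
  - {category: opioids, aggregation: mean_of_alternatives}
  - {category: antibiotics, aggregation: mean_of_alternatives}
  - {category: corticosteroids, aggregation: mean_of_alternatives}
  - {category: other, aggregation: sum_of_lines}
material_items:
  - {label: Big clamp, quantity: "2.33", weighted_cost_override: "58.41"}
  - {label: Electrosurgical knife, quantity: "1.00", weighted_cost_override: "14.34"}
  - {label: Scalpel, quantity: "2.00", weighted_cost_override: "30.77"}
  - {label: Surgical strips, quantity: "10.00", weighted_cost_override: "1.81"}
  - {label: Suture thread, quantity: "2.88", weighted_cost_override: "17.25"}
  - {label: Gauze, quantity: "9.38", weighted_cost_override: "0.93"}
  - {label: Surgical drape, quantity: "2.50", weighted_cost_override: "5.39"}
  - {label: Dressing 8x15, quantity: "1.00", weighted_cost_override: "0.54"}
  - {label: Surgical swab, quantity: "2.83", weighted_cost_override: "6.23"}
  - {label: Sterile material pack, quantity: "1.00", weighted_cost_override: "24.52"}
  - {label: Vicryl suture, quantity: "1.50", weighted_cost_override: "9.00"}
  - {label: Monocryl suture, quantity: "2.00", weighted_cost_override: "14.50"}
  - {label: Jackson-Pratt drain, quantity: "0.93", weighted_cost_override: "2.85"}
  - {label: Hemovac drain, quantity: "2.00", weighted_cost_override: "13.00"}
staff_lines:
  - {role: Physician, headcount: "2.00", cost: "95.58"}
  - {role: Nurse, headcount: "1.30", cost: "28.75"}
  - {role: Anesthetist, headcount: "1.00", cost: "47.79"}
  - {role: Healthcare assistant, headcount: "0.80", cost: "38.23"}
  - {role: Surgical instrument technician, headcount: "1.00", cost: "22.11"}
facility:
  or_minutes: "82.50"
  or_cost: "1685.28"
  stay_days: "2.40"
  stay_cost: "1617.60"
  stay_rate_per_day: "674.00"
followup_courses:
  - name: standard
    frequency: "0.93"
    printed_total: "143.04"
    items:
      - {label: Specialist consultation, quantity: "1.25", weighted_cost_override: "25.83"}
      - {label: CBC, quantity: "0.33", weighted_cost_override: "1.06"}
      - {label: Serum calcium, quantity: "1.00", weighted_cost_override: "1.13"}
      - {label: TSH, quantity: "1.00", weighted_cost_override: "5.46"}
      - {label: FT4, quantity: "1.00", weighted_cost_override: "6.36"}
      - {label: Histological exam, quantity: "1.00", weighted_cost_override: "27.17"}
      - {label: Neck ultrasound, quantity: "1.00", weighted_cost_override: "28.41"}
      - {label: Levothyroxine therapy, unit_cost: "47.63"}  # flat annual cost
  - name: acute_complications
    frequency: "0.035"
    printed_total: "258.97"
    items:
      - {label: Endocrinology consultation, quantity: "1.88", weighted_cost_override: "38.74"}
      - {label: Surgical consultation, quantity: "1.50", weighted_cost_override: "30.99"}
      - {label: Serum calcium, quantity: "1.00", weighted_cost_override: "1.13"}
      - {label: Calcium infusion, quantity: "0.50", weighted_cost_override: "1.78"}
      - {label: CBC, quantity: "1.17", weighted_cost_override: "3.70"}
      - {label: Neck ultrasound, quantity: "1.38", weighted_cost_override: "39.06"}
      - {label: Histological examination, quantity: "0.78", weighted_cost_override: "21.13"}
      - {label: Video-laryngoscopy, quantity: "1.00", weighted_cost_override: "27.11"}
      - {label: FT4, quantity: "1.00", weighted_cost_override: "6.36"}
      - {label: Levothyroxine therapy, unit_cost: "47.63"}
      - {label: Cost of reintervention, quantity: "0.01", weighted_cost_override: "37.46"}
  - name: chronic_complications
    frequency: "0.035"
    printed_total: "297.22"
    items:
      - {label: Endocrinology consultation, quantity: "2.00", weighted_cost_override: "41.32"}
      - {label: Surgical consultation, quantity: "1.25", weighted_cost_override: "25.83"}
      - {label: Speech therapy, quantity: "7.50", weighted_cost_override: "110.42"}
      - {label: FT4, quantity: "1.00", weighted_cost_override: "6.36"}
      - {label: CBC, quantity: "1.00", weighted_cost_override: "3.17"}
      - {label: Histological examination, quantity: "1.00", weighted_cost_override: "27.17"}
      - {label: Video-laryngoscopy, quantity: "1.00", weighted_cost_override: "27.11"}
      - {label: Calcium/vitamin D, quantity: "1.00", weighted_cost_override: "3.57"}
      - {label: Levothyroxine therapy, unit_cost: "47.63"}
indirect:
  hosp_days: "2.40"
  convalescence_days: "11.22"
  hours_lost_per_day: "5"
  hourly_wage: "14.05"
  caregiver_share: "0.05"
  printed_patient_loss: "956.84"
  printed_caregiver_loss: "47.84"
retreatment_rate: "0"
printed_phase_totals:
  prehospitalization: "281.80"
  drugs: "11.49"
  personnel: "232.47"
summary_reference:
  prehospitalization: "281.80"
  drugs: "11.49"
  materials: "199.54"
  personnel: "232.47"
  operating_room: "1685.28"
  hospital_stay: "1617.60"
  procedure_subtotal: "3746.39"
  followup_weighted.standard: "133.03"
  followup_weighted.acute_complications: "9.06"
  followup_weighted.chronic_complications: "10.40"
  followup_subtotal: "152.50"
  productivity: "1004.68"
  grand_total.societal: "5185.36"
  grand_total.opportunity_cost_societal: "4952.90"
  # the materials-table total row is a documented erratum: its own column
  # (items + operating room + stay) sums 13.00 higher
  materials_table_total: "3489.42"
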