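{
  "description": "Published clinical cohort: 11 patients treated with single-field electron beams for skin lesions of the eye canthi, each with a TPS-designed reference bolus fabricated both by FDM 3D printing (ABS, 1.05 g/cm3) and by hand-layered 1.5 mm paraffin sheets. Volumes are in cm3 as reported (rounded to 0.1 cm3); ML in percent; dose differences are signed percent per metric relative to the reference-bolus plan.",
  "prescription": {"dose_gy": 60.0, "fractions": 30, "ctv_to_ptv_margin_mm": 3.0},
  "patients": [
    {
      "id": 1, "diagnosis": "basal cell carcinoma", "site": "inner canthus",
      "ptv_volume_cm3": 1.00, "field": "circle 3.0", "energy_mev": [6], "ptv_max_depth_cm": 0.56,
      "v1_printed_cm3": 6.8, "v1_paraffin_cm3": 5.8, "vr_cm3": 7.0,
      "v2_printed_cm3": 6.9, "v2_paraffin_cm3": 20.7,
      "ml_printed_pct": 96.2, "ml_paraffin_pct": 23.5,
      "dd_near_min_printed": 5.0, "dd_near_min_paraffin": 9.0,
      "dd_mean_printed": 2.5, "dd_mean_paraffin": 4.0,
      "dd_near_max_printed": 2.0, "dd_near_max_paraffin": 2.5
    },
    {
      "id": 2, "diagnosis": "basal cell carcinoma", "site": "inner canthus",
      "ptv_volume_cm3": 2.63, "field": "circle 3.0", "energy_mev": [6], "ptv_max_depth_cm": 1.10,
      "v1_printed_cm3": 3.5, "v1_paraffin_cm3": 2.5, "vr_cm3": 3.8,
      "v2_printed_cm3": 3.5, "v2_paraffin_cm3": 3.3,
      "ml_printed_pct": 92.8, "ml_paraffin_pct": 49.9,
      "dd_near_min_printed": -1.0, "dd_near_min_paraffin": 3.0,
      "dd_mean_printed": -0.5, "dd_mean_paraffin": 2.0,
      "dd_near_max_printed": 1.5, "dd_near_max_paraffin": 2.5
    },
    {
      "id": 3, "diagnosis": "basal cell carcinoma", "site": "outer canthus (lower eyelid)",
      "ptv_volume_cm3": 7.53, "field": "rect 6.7x3.9", "energy_mev": [6, 9], "ptv_max_depth_cm": 1.80,
      "v1_printed_cm3": 18.5, "v1_paraffin_cm3": 16.0, "vr_cm3": 20.0,
      "v2_printed_cm3": 18.5, "v2_paraffin_cm3": 23.9,
      "ml_printed_pct": 92.5, "ml_paraffin_pct": 53.6,
      "dd_near_min_printed": -3.5, "dd_near_min_paraffin": 24.0,
      "dd_mean_printed": 2.0, "dd_mean_paraffin": 5.0,
      "dd_near_max_printed": -0.5, "dd_near_max_paraffin": -4.0
    },
    {
      "id": 4, "diagnosis": "basal cell carcinoma", "site": "inner canthus",
      "ptv_volume_cm3": 5.99, "field": "rect 3.5x3.2", "energy_mev": [6], "ptv_max_depth_cm": 1.00,
      "v1_printed_cm3": 7.0, "v1_paraffin_cm3": 4.7, "vr_cm3": 7.1,
      "v2_printed_cm3": 7.1, "v2_paraffin_cm3": 4.7,
      "ml_printed_pct": 98.3, "ml_paraffin_pct": 66.6,
      "dd_near_min_printed": 0.0, "dd_near_min_paraffin": -2.0,
      "dd_mean_printed": -0.5, "dd_mean_paraffin": -2.0,
      "dd_near_max_printed": 0.0, "dd_near_max_paraffin": -4.0
    },
    {
      "id": 5, "diagnosis": "basal cell carcinoma", "site": "inner canthus",
      "ptv_volume_cm3": 2.39, "field": "circle 3.0", "energy_mev": [9], "ptv_max_depth_cm": 2.00,
      "v1_printed_cm3": 1.4, "v1_paraffin_cm3": 1.0, "vr_cm3": 1.4,
      "v2_printed_cm3": 1.4, "v2_paraffin_cm3": 2.5,
      "ml_printed_pct": 94.4, "ml_paraffin_pct": 28.5,
      "dd_near_min_printed": 0.5, "dd_near_min_paraffin": 4.0,
      "dd_mean_printed": 0.5, "dd_mean_paraffin": 1.5,
      "dd_near_max_printed": 1.5, "dd_near_max_paraffin": 8.0
    },
    {
      "id": 6, "diagnosis": "basal cell carcinoma", "site": "inner canthus",
      "ptv_volume_cm3": 1.51, "field": "circle 3.2", "energy_mev": [6], "ptv_max_depth_cm": 1.00,
      "v1_printed_cm3": 2.3, "v1_paraffin_cm3": 1.8, "vr_cm3": 2.4,
      "v2_printed_cm3": 2.3, "v2_paraffin_cm3": 2.7,
      "ml_printed_pct": 94.9, "ml_paraffin_pct": 50.3,
      "dd_near_min_printed": 0.0, "dd_near_min_paraffin": 2.0,
      "dd_mean_printed": 0.5, "dd_mean_paraffin": 2.0,
      "dd_near_max_printed": 1.5, "dd_near_max_paraffin": 5.0
    },
    {
      "id": 7, "diagnosis": "basal cell carcinoma", "site": "inner canthus",
      "ptv_volume_cm3": 2.14, "field": "circle 3.1", "energy_mev": [6], "ptv_max_depth_cm": 0.84,
      "v1_printed_cm3": 6.1, "v1_paraffin_cm3": 5.0, "vr_cm3": 6.2,
      "v2_printed_cm3": 6.1, "v2_paraffin_cm3": 10.0,
      "ml_printed_pct": 98.4, "ml_paraffin_pct": 40.3,
      "dd_near_min_printed": 1.0, "dd_near_min_paraffin": 4.5,
      "dd_mean_printed": 1.0, "dd_mean_paraffin": 3.0,
      "dd_near_max_printed": 2.0, "dd_near_max_paraffin": 5.0
    },
    {
      "id": 8, "diagnosis": "squamous cell carcinoma", "site": "inner canthus and lower eyelid",
      "ptv_volume_cm3": 10.00, "field": "rect 7.5x6.6", "energy_mev": [9], "ptv_max_depth_cm": 2.60,
      "v1_printed_cm3": 14.0, "v1_paraffin_cm3": 10.0, "vr_cm3": 15.0,
      "v2_printed_cm3": 14.0, "v2_paraffin_cm3": 14.3,
      "ml_printed_pct": 93.3, "ml_paraffin_pct": 46.7,
      "dd_near_min_printed": 5.0, "dd_near_min_paraffin": 7.0,
      "dd_mean_printed": 2.0, "dd_mean_paraffin": 4.0,
      "dd_near_max_printed": 2.5, "dd_near_max_paraffin": 3.0
    },
    {
      "id": 9, "diagnosis": "squamous cell carcinoma", "site": "inner canthus and lower eyelid",
      "ptv_volume_cm3": 7.51, "field": "rect 5.8x4.3", "energy_mev": [9], "ptv_max_depth_cm": 1.56,
      "v1_printed_cm3": 10.5, "v1_paraffin_cm3": 7.0, "vr_cm3": 11.0,
      "v2_printed_cm3": 10.6, "v2_paraffin_cm3": 10.8,
      "ml_printed_pct": 94.5, "ml_paraffin_pct": 41.4,
      "dd_near_min_printed": -0.5, "dd_near_min_paraffin": 4.0,
      "dd_mean_printed": -0.5, "dd_mean_paraffin": 2.0,
      "dd_near_max_printed": 2.0, "dd_near_max_paraffin": 3.0
    },
    {
      "id": 10, "diagnosis": "basal cell carcinoma", "site": "inner canthus and lower eyelid",
      "ptv_volume_cm3": 1.17, "field": "rect 3.9x2.5", "energy_mev": [6], "ptv_max_depth_cm": 0.70,
      "v1_printed_cm3": 1.7, "v1_paraffin_cm3": 1.5, "vr_cm3": 1.8,
      "v2_printed_cm3": 1.7, "v2_paraffin_cm3": 2.5,
      "ml_printed_pct": 94.4, "ml_paraffin_pct": 50.8,
      "dd_near_min_printed": -2.0, "dd_near_min_paraffin": 7.0,
      "dd_mean_printed": 1.5, "dd_mean_paraffin": 3.0,
      "dd_near_max_printed": -0.5, "dd_near_max_paraffin": -4.0
    },
    {
      "id": 11, "diagnosis": "basal cell carcinoma", "site": "inner canthus",
      "ptv_volume_cm3": 1.30, "field": "circle 3.0", "energy_mev": [6], "ptv_max_depth_cm": 0.60,
      "v1_printed_cm3": 6.8, "v1_paraffin_cm3": 5.1, "vr_cm3": 7.0,
      "v2_printed_cm3": 6.9, "v2_paraffin_cm3": 6.8,
      "ml_printed_pct": 96.2, "ml_paraffin_pct": 54.6,
      "dd_near_min_printed": 0.5, "dd_near_min_paraffin": 2.0,
      "dd_mean_printed": 0.5, "dd_mean_paraffin": 2.0,
      "dd_near_max_printed": 2.0, "dd_near_max_paraffin": 5.0
    }
  ],
  "reported_column_summaries": {
    "ml_printed_pct": {"mean": 95.1, "sd": 2.1},
    "ml_paraffin_pct": {"mean": 46.0, "sd": 10.1},
    "dd_near_min_printed": {"median": 0.0, "q1": -1.0, "q3": 1.0},
    "dd_near_min_paraffin": {"median": 7.0, "q1": 2.0, "q3": 7.0,
      "note": "reported median does not recompute from the column values (4.0 under any standard rule); the quartiles do"},
    "dd_mean_printed": {"mean": 0.8, "sd": 1.1},
    "dd_mean_paraffin": {"mean": 2.4, "sd": 1.8},
    "dd_near_max_printed": {"median": 1.5, "q1": 0.0, "q3": 2.0},
    "dd_near_max_paraffin": {"median": 3.0, "q1": -4.0, "q3": 5.0}
  }
}
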