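{
  "version": 1,
  "description": "Five single-fraction stereotactic-radiosurgery cases (MRI-measured metastatic brain tumors). Shared settings: alpha/beta = 10 Gy, tau_rad = 8 d, T* = 1 d, T_m = 10 d. The treatment-day entries of the two source tables disagree for cases 3 and 4; the value printed beside the model parameters is the default and the alternate reading is kept in metadata (alt_t_r_days). td_at_treatment_days is the printed doubling time at treatment, used as the growth-rate override when reproducing the response-ratio endpoint.",
  "cases": [
    {
      "label": "clinical-1",
      "growth": {"v0_cm3": 0.126, "td0_days": 29.0, "theta": 0.62},
      "radio": {"alpha": 0.09, "alpha_beta": 10.0, "t_star": 1.0, "t_m": 10.0},
      "treatment": {"dose_gy": 38.3, "t_r_days": 34.0, "tau_rad_days": 8.0, "t_cl_days": 13.0},
      "td_at_treatment_days": 32.6,
      "metadata": {
        "local_control": "CR",
        "primary": "NSCL",
        "printed_r40": 0.16,
        "printed_v_at_treatment_cm3": 0.268,
        "monitor_duration_days": 137
      }
    },
    {
      "label": "clinical-2",
      "growth": {"v0_cm3": 0.0065, "td0_days": 6.0, "theta": 0.77},
      "radio": {"alpha": 0.19, "alpha_beta": 10.0, "t_star": 1.0, "t_m": 10.0},
      "treatment": {"dose_gy": 21.2, "t_r_days": 117.0, "tau_rad_days": 8.0, "t_cl_days": 38.0},
      "td_at_treatment_days": 28.0,
      "metadata": {
        "local_control": "PR",
        "primary": "RCC",
        "printed_r40": 0.57,
        "printed_v_at_treatment_cm3": 0.392,
        "monitor_duration_days": 680
      }
    },
    {
      "label": "clinical-3",
      "growth": {"v0_cm3": 0.271, "td0_days": 9.0, "theta": 0.53},
      "radio": {"alpha": 0.19, "alpha_beta": 10.0, "t_star": 1.0, "t_m": 10.0},
      "treatment": {"dose_gy": 26.0, "t_r_days": 22.0, "tau_rad_days": 8.0, "t_cl_days": 40.0},
      "td_at_treatment_days": 11.2,
      "metadata": {
        "local_control": "PR",
        "primary": "RCC",
        "printed_r40": 0.58,
        "printed_v_at_treatment_cm3": 0.662,
        "monitor_duration_days": 276,
        "alt_t_r_days": 137.0,
        "t_r_note": "source tables disagree on the treatment day (22 vs 137); 22 is the default"
      }
    },
    {
      "label": "clinical-4",
      "growth": {"v0_cm3": 0.031, "td0_days": 6.6, "theta": 0.78},
      "radio": {"alpha": 0.1, "alpha_beta": 10.0, "t_star": 1.0, "t_m": 10.0},
      "treatment": {"dose_gy": 22.0, "t_r_days": 78.0, "tau_rad_days": 8.0, "t_cl_days": 10.0},
      "td_at_treatment_days": 16.1,
      "metadata": {
        "local_control": "SD",
        "primary": "Testicular",
        "printed_r40": 0.69,
        "printed_v_at_treatment_cm3": 6.933,
        "monitor_duration_days": 106,
        "alt_t_r_days": 8.0,
        "t_r_note": "source tables disagree on the treatment day (78 vs 8); 78 is the default"
      }
    },
    {
      "label": "clinical-5",
      "growth": {"v0_cm3": 0.101, "td0_days": 7.8, "theta": 0.99},
      "radio": {"alpha": 0.05, "alpha_beta": 10.0, "t_star": 1.0, "t_m": 10.0},
      "treatment": {"dose_gy": 24.3, "t_r_days": 29.0, "tau_rad_days": 8.0, "t_cl_days": 20.0},
      "td_at_treatment_days": 7.9,
      "metadata": {
        "local_control": "PD",
        "primary": "Melanoma",
        "printed_r40": 10.0,
        "printed_v_at_treatment_cm3": 1.314,
        "monitor_duration_days": 80
      }
    }
  ]
}
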