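{
  "version": 1,
  "description": "Rat rhabdomyosarcoma single-fraction dose series (caliper-measured volumes). Shared settings: v0 = 0.0157 cm3, irradiation on day 11, Td(0) = 1.35 d, T_cl = 4 d, tau_rad = 8 d, alpha/beta = 10 Gy, T* = 1 d, T_m = 10 d. The control column has no alpha (stored as 0; dose is 0 so it never enters).",
  "cases": [
    {
      "label": "rat-control",
      "growth": {"v0_cm3": 0.0157, "td0_days": 1.35, "theta": 0.72},
      "radio": {"alpha": 0.0, "alpha_beta": 10.0, "t_star": 1.0, "t_m": 10.0},
      "treatment": {"dose_gy": 0.0, "t_r_days": 11.0, "tau_rad_days": 8.0, "t_cl_days": 4.0},
      "metadata": {"dose_rad": 0, "n_points": 11, "msd_printed": 0.01883}
    },
    {
      "label": "rat-1000",
      "growth": {"v0_cm3": 0.0157, "td0_days": 1.35, "theta": 0.72},
      "radio": {"alpha": 0.3, "alpha_beta": 10.0, "t_star": 1.0, "t_m": 10.0},
      "treatment": {"dose_gy": 10.0, "t_r_days": 11.0, "tau_rad_days": 8.0, "t_cl_days": 4.0},
      "metadata": {"dose_rad": 1000, "n_points": 11, "msd_printed": 0.01099}
    },
    {
      "label": "rat-2000",
      "growth": {"v0_cm3": 0.0157, "td0_days": 1.35, "theta": 0.74},
      "radio": {"alpha": 0.2, "alpha_beta": 10.0, "t_star": 1.0, "t_m": 10.0},
      "treatment": {"dose_gy": 20.0, "t_r_days": 11.0, "tau_rad_days": 8.0, "t_cl_days": 4.0},
      "metadata": {"dose_rad": 2000, "n_points": 19, "msd_printed": 0.00816}
    },
    {
      "label": "rat-3000",
      "growth": {"v0_cm3": 0.0157, "td0_days": 1.35, "theta": 0.795},
      "radio": {"alpha": 0.16, "alpha_beta": 10.0, "t_star": 1.0, "t_m": 10.0},
      "treatment": {"dose_gy": 30.0, "t_r_days": 11.0, "tau_rad_days": 8.0, "t_cl_days": 4.0},
      "metadata": {"dose_rad": 3000, "n_points": 18, "msd_printed": 0.00832}
    },
    {
      "label": "rat-4000",
      "growth": {"v0_cm3": 0.0157, "td0_days": 1.35, "theta": 0.838},
      "radio": {"alpha": 0.145, "alpha_beta": 10.0, "t_star": 1.0, "t_m": 10.0},
      "treatment": {"dose_gy": 40.0, "t_r_days": 11.0, "tau_rad_days": 8.0, "t_cl_days": 4.0},
      "metadata": {"dose_rad": 4000, "n_points": 14, "msd_printed": 0.03039}
    }
  ]
}
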