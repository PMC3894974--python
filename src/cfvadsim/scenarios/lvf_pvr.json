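{
 "name": "lvf_pvr",
 "lv": {
  "lambda_asc": 1.0516413701702991,
  "lambda_desc": -0.7141696069429927,
  "V_transition": 157.29153845,
  "V0": 10.0,
  "A_ed": 2.3833169003793824,
  "B_ed": 0.01110825865506927,
  "Rv_coeff": 0.00039911608185629836,
  "Ts_frac": 0.425,
  "P_int": null,
  "rv_constant": false
 },
 "rv": {
  "lambda_asc": 0.8079743499867255,
  "lambda_desc": -0.4,
  "V_transition": 200.0,
  "V0": 10.0,
  "A_ed": 0.25,
  "B_ed": 0.025555964677797686,
  "Rv_coeff": 0.0002,
  "Ts_frac": 0.425,
  "P_int": null,
  "rv_constant": false
 },
 "septum": {
  "Es_sys": 48.0,
  "Es_dia": 1.0
 },
 "vascular": {
  "R_mitral": 0.0035,
  "R_aortic": 0.004,
  "R_tricuspid": 0.0025,
  "R_pulmonic": 0.003,
  "C_sa": 0.9603738711504339,
  "R_sa": 0.06,
  "L_sa": 0.0003,
  "Vu_sa": 600.0,
  "C_sp": 2.5,
  "R_sp": 0.9322186773680915,
  "Vu_sp": 250.0,
  "C_sv": 65.0,
  "Vu_sv": 2700.0,
  "C_pa": 3.538261414852666,
  "R_pa": 0.025,
  "L_pa": 0.0003,
  "Vu_pa": 90.0,
  "C_pp": 5.0,
  "R_pp": 0.517,
  "Vu_pp": 120.0,
  "C_pv": 20.0,
  "Vu_pv": 300.0,
  "total_blood_volume": 5700.0,
  "heart_rate": 85.0
 },
 "baroreflex": {
  "P_set": 95.0,
  "k_s": 11.0,
  "g_R_hypo": 0.62,
  "g_R_hyper": 0.18,
  "g_E": 0.15,
  "Vu_span": 700.0,
  "tau_R": 6.0,
  "tau_Vu": 20.0,
  "tau_E": 8.0,
  "enabled": true
 },
 "pump": {
  "beta0": 0.1707,
  "beta1": 0.02177,
  "beta2": 9.03e-05,
  "R_in": 0.0677,
  "R_out": 0.0677,
  "L_in": 0.0127,
  "L_out": 0.0127,
  "P_th": 1.0,
  "k_suc": 3.5
 },
 "BSA": 1.9,
 "pump_speed_schedule": null,
 "integration": {
  "dt": 0.0001,
  "sample_dt": 0.001,
  "max_beats": 400,
  "min_beats": 12,
  "conv_tol": 0.002,
  "n_report_beats": 5,
  "diode_eps": 0.01
 }
}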