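# Default parameter set of the T-lymphocyte calcium model (Jurkat cell).
# Units are spelled out in the key names; values are converted to the
# internal unit system (uM, S, A, s) on load.  The steady-state-derived
# entries (gamma_P_per_s, pmca rho, ip3r rho, crac rho_minus) are stated
# here for reference and are verified against the closure at load time.
geometry:
  R_cell_um: 8.0        # cell radius (from 2 pl Jurkat cell volume)
  f_R: 0.25             # nucleus radius fraction
  f_V: 0.01             # ER volume fraction
  f_A: 30.0             # ER surface folding factor
  C_m_pF_per_um2: 0.028 # specific membrane capacitance
potentials:
  T_K: 310.0
  V0_mV: -60.0
  V_ER0_mV: -60.0
  dV_C_mV: 78.0         # CRAC reversal-potential shift
  dV_CER_mV: 63.0       # ER/IP3R reversal-potential shift (fitted)
  C_ext_mM: 2.0
resting:
  C0_uM: 0.1
  C_ER0_mM: 0.4
buffers:
  b0_uM: 100.0          # cytosolic binding sites (25 uM calmodulin x 4)
  K_b_uM: 0.1
  b_ER0_mM: 30.0        # ER calreticulin sites
  K_ERb_mM: 0.1
ip3:
  P0_nM: 8.7            # resting IP3 (fitted)
  beta_P_nM_per_s: 0.6  # production rate (fitted)
  gamma_P_per_s: 0.01149  # derived by steady state
  C_P_uM: 0.5
  n_P: 1.0
crac:
  g_bar_fS: 2.0
  rho0_per_um2: 0.6     # resting active density (fitted)
  rho_plus_per_um2: 3.9 # maximal active density (fitted, 6.5-fold)
  rho_minus_per_um2: 0.5115  # derived by steady state
  C_CRAC_uM: 169.0
  n_CRAC: 4.2
  tau_CRAC_s: 5.0
ip3r:
  g_bar_pS: 0.064
  g_max: 0.81
  C_act_uM: 0.21
  n_act: 1.9
  n_inh: 3.9
  C_inh_bar_uM: 52.0
  n_C: 4.0
  P_half_uM: 0.05
  tau_act_s: 0.1
  theta_inh_s: 0.3
  rho_per_um2: 11.35    # derived by steady state
pmca:
  I_bar_pA: 1.0e-05     # 30 Hz turnover, 2 charges per cycle
  C_half_uM: 0.2        # isoform 4b
  n: 2.0
  tau_s: 50.0           # delayed activation of 4b
  rho_per_um2: 68.57    # derived by steady state
serca:
  I_bar_pA: 3.0e-06     # 5 Hz turnover of SERCA2b, 2 calcium per cycle
  C_half_uM: 0.25       # isoform 2b
  n: 2.0
  rho_per_um2: 700.0    # fitted
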