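# Default rate constants of the lac switch model, one block per inducer.
# Units: second-order rates M^-1 s^-1, first-order rates s^-1, V in liters,
# T_double in seconds. Second-order rates are molar and are converted to
# stochastic propensities with k/(N_A*V) at build time.
TMG:
  k_rb: 2.43e+6
  k_ro_off: 6.30e-4
  k_iro_off: 6.30e-4
  k_i2ro_off: 3.15e-1
  k_ts: 1.26e-1
  k_tl: 4.44e-2
  k_mdeg: 1.11e-2
  k_pdeg: 2.10e-4
  inducer_on_free_1: 2.27e+4
  inducer_on_free_2: 1.14e+4
  inducer_off_free_1: 2.0e-1
  inducer_off_free_2: 4.0e-1
  inducer_on_cplx_1: 6.67e+2
  inducer_on_cplx_2: 3.33e+2
  inducer_off_cplx_1: 1.0
  inducer_off_cplx_2: 2.0
  k_diff_in: 2.33e-3
  k_diff_out: 2.33e-3
  k_y_on: 3.03e+4
  k_y_off: 1.2e-1
  k_cat: 1.2e+1
  C: 0.5
  C2: 0.01
  R_tot: 10
  V: 8.0e-16
  T_double: 3300.0
  inducer: TMG
IPTG:
  k_rb: 2.43e+6
  k_ro_off: 6.30e-4
  k_iro_off: 6.30e-4
  k_i2ro_off: 3.15e-1
  k_ts: 1.26e-1
  k_tl: 4.44e-2
  k_mdeg: 1.11e-2
  k_pdeg: 2.10e-4
  inducer_on_free_1: 9.71e+4
  inducer_on_free_2: 4.85e+4
  inducer_off_free_1: 2.0e-1
  inducer_off_free_2: 4.0e-1
  inducer_on_cplx_1: 2.24e+4
  inducer_on_cplx_2: 1.12e+4
  inducer_off_cplx_1: 1.0
  inducer_off_cplx_2: 2.0
  k_diff_in: 2.33e-3
  k_diff_out: 2.33e-3
  k_y_on: 3.03e+4
  k_y_off: 1.2e-1
  k_cat: 1.2e+1
  C: 0.5
  C2: 0.01
  R_tot: 10
  V: 8.0e-16
  T_double: 3300.0
  inducer: IPTG
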