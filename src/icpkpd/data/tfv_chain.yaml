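# Typical population values for the tenofovir chain:
# plasma TFV -> intracellular TFV-DP -> deoxypurines dATP/dGTP.
# Rates are /day, volumes L, clearances L/day; intracellular and dNTP
# levels fmol/10^6 PBMC; the recycling fraction R is stored as a fraction.
analyte: TFV
dose_ug: 136000.0            # one TDF 300 mg tablet = 136 mg tenofovir
plasma:
  Ka: 80.1
  Vc_F: 390.0
  CL_F: 1410.0
  Vp_F: 877.0
  Q_F: 5390.0
intracellular:
  Kf: 1.4
  SC50: 6.55
  Kel: 0.228
  R: 0.0582
dntp:
  dATP:
    R0: 155.0
    EC50: 1020.0
  dGTP:
    R0: 245.0
    EC50: 54.6
    gamma: 0.928             # transient effect: inhibition wanes as 1/(1+t^gamma)
covariates: []
variability:
  omega2:
    plasma.Vc_F: 0.288
    plasma.CL_F: 0.117
    plasma.Q_F: 0.0693
    ic.Kf: 0.238
    ic.Kel: 0.316
    dntp.dATP.R0: 0.220
    dntp.dATP.EC50: 1.70
    dntp.dGTP.R0: 0.203
  sigma2:
    TFV: 0.0745
    TFVDP: 0.115
    dATP: 0.258
    dGTP: 0.267              # from the printed 51.7 %CV (variance cell blank)
  error_model:
    TFV: exponential
    TFVDP: proportional
    dATP: exponential
    dGTP: exponential
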