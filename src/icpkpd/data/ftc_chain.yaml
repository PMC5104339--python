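# Typical population values for the emtricitabine chain:
# plasma FTC -> intracellular FTC-TP -> deoxypyrimidines dCTP/TTP.
# Covariate model: males have a larger plasma central volume
# (Vc/F = 99.4 + 24.3*sex) and HIV-positive subjects a faster anabolite
# formation rate (Kf = 41.6 + 31.3*hiv).
analyte: FTC
dose_ug: 200000.0            # one FTC 200 mg tablet
plasma:
  Ka: 55.7
  Vc_F: 99.4
  CL_F: 482.0
  Vp_F: 166.0
  Q_F: 141.0
intracellular:
  Kf: 41.6
  SC50: 3320.0
  Kel: 1.6
  R: 0.16
dntp:
  dCTP:
    R0: 771.0
    EC50: 44400.0
  TTP:
    R0: 335.0
    EC50: 18800.0
covariates:
  - param: plasma.Vc_F
    covariate: sex
    coeff: 24.3
  - param: ic.Kf
    covariate: hiv
    coeff: 31.3
variability:
  omega2:
    plasma.Vc_F: 0.0319
    plasma.CL_F: 0.0942
    plasma.Vp_F: 0.0335
    ic.Kf: 0.0358
    ic.Kel: 0.0561
    dntp.dCTP.R0: 0.195
    dntp.dCTP.EC50: 0.68
    dntp.TTP.R0: 0.383
    dntp.TTP.EC50: 1.02
  sigma2:
    FTC: 0.122
    FTCTP: 0.0942
    dCTP: 0.229
    TTP: 0.356
  error_model:
    FTC: exponential
    FTCTP: proportional
    dCTP: exponential
    TTP: exponential
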