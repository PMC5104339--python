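# icpkpd

Population pharmacokinetic/pharmacodynamic simulator for co-formulated oral
tenofovir disoproxil fumarate / emtricitabine (TDF/FTC), linking three layers
per analyte:

1. **Plasma drug** (TFV or FTC): two-compartment disposition with first-order
   absorption, in ng/mL.
2. **Intracellular anabolite** (TFV-DP or FTC-TP in PBMC, fmol/10⁶ cells):
   formed from the plasma concentration through a hybrid of first-order
   formation and saturation, eliminated biphasically through a "recycle"
   compartment.
3. **Endogenous dNTP pool** (dATP/dGTP for TFV, dCTP/TTP for FTC): turnover
   models whose production is inhibited by the anabolite.

The plasma→cell link moves *information*, not mass: the plasma concentration
C = A₂/(V_c/F) drives the anabolite formation rate, attenuated by a virtual
saturation compartment,

    dA₄/dt = K_f·C / (1 + A₅/SC₅₀) − K_el·A₄ + A₆·K_el·R
    dA₅/dt = K_f·C − (CL/V_c)·A₅
    dA₆/dt = A₄·K_el·R − A₆·K_el·R

with the recycling fraction R splitting intracellular elimination into a net
loss (1−R)·K_el and a slow exchange R·K_el that produces the long terminal
phase of TFV-DP.  Each dNTP follows an indirect-response model,

    dA₇/dt = K⁰_in·(1 − E_max·A₄/(A₄+EC₅₀)) − K_out·A₇ ,  K⁰_in = R₀·K_out,

with E_max = K_out = 1 fixed; the transient dGTP effect carries an extra
waning factor 1/(1+t^γ).  Published typical values, covariate models
(sex on FTC V_c/F, HIV status on FTC-TP K_f), lognormal interindividual
variability and per-stream residual-error models ship as built-in parameter
sets (`tfv_chain.default`, `ftc_chain.default`).

On top of the ODE core the package provides:

- **Virtual populations and synthetic trials** that emulate an intensive
  first-dose-to-steady-state design (21 HIV−/19 HIV+ subjects, rich and
  sparse visits, washout, per-sample LLOQ censoring with BLQ treated as
  missing), plus a simulation-based predictive check (VPC-style coverage).
- **Sequential-link estimation** (plasma → intracellular → dNTP) by pooled
  nonlinear least squares on the error-model scale, with an empirical-Bayes
  per-subject step and a likelihood-ratio covariate-decision utility.
- **Kinetic summaries**: closed-form phase half-lives, and the *operational
  multiple-dosing half-life* — the dosing interval τ at which a steady-state
  accumulation ratio (Cmax,ss:Cmax,fd or Cmax,ss:Cmin,ss) equals 2, found by
  simulating 50-dose regimens over a τ grid.
- **On-demand PrEP simulation**: Monte-Carlo analog:dNTP molar-ratio time
  courses under event-driven dosing (double dose 2–24 h before coitus,
  single doses +24 h and +48 h after), with threshold-exceedance summaries
  against in-vitro ratio EC₅₀/EC₉₀ values.

## Worked example

Phase half-lives of the tenofovir chain from the built-in typical values:

```python
>>> from icpkpd import default_chains
>>> from icpkpd.halflife import plasma_halflives, ic_halflives
>>> tfv = default_chains()["TFV"].params
>>> round(plasma_halflives(tfv.plasma).beta_hours, 1)   # plasma terminal
16.9
>>> hl = ic_halflives(tfv.ic)
>>> round(hl.alpha_hours, 1), round(hl.beta_days, 1)    # TFV-DP phases
(72.7, 55.7)
```

The plasma TFV terminal half-life is ~17 h, while intracellular TFV-DP decays
with a fast phase of ~3 days and a shallow terminal phase of ~56 days carried
by the small (5.8%) recycling fraction.  Because the plasma→cell link is
nonlinear, a *dosing* half-life is better captured operationally:

```bash
$ icpkpd ophalf --chain tfvdp --criterion max_over_min --out out/op
t1/2,op (tfvdp, max_over_min) = 6.742 days = 161.8 hours
```

i.e. dosing TFV every ~6.7 days would leave 50% peak-to-trough loss at steady
state.  An on-demand PrEP simulation (200 virtual HIV-negative subjects,
double dose 24 h pre-coitus):

```bash
$ icpkpd prep --n 200 --offset-hours 24 --seed 1 --out out/prep
{
  "tfvdp_datp_above_ec50_at_coitus_pct": 92.0,
  "ftctp_dctp_above_ec90_at_coitus_pct": 100.0,
  "ftctp_dctp_above_ec50_at_coitus_pct": 100.0
}
```

Most subjects clear the TFV-DP:dATP protective ratio threshold (0.086) at
coitus with a 24-h lead, and essentially all clear both FTC-TP:dCTP
thresholds — the emtricitabine anabolite accumulates much faster, which is
why it carries the early protective effect of on-demand dosing.  Other
subcommands: `synth` (synthetic trial datasets), `fit` (sequential-link
stages), `vpc` (predictive check), `simulate` (typical-value trajectories).

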