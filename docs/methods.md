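# Methods

## Model structure and assumptions

Each analyte chain (tenofovir and emtricitabine) is a seven-state ODE system
integrated in days.

**Plasma.** First-order absorption from a depot (A₁) into a two-compartment
disposition system (A₂ central, A₃ peripheral), parameterized by apparent
values K_a, V_c/F, CL/F, V_p/F, Q/F.  Doses are bolus additions of
parent-drug-equivalent mass to the depot: one tablet is 136,000 µg TFV
(TDF 300 mg delivers 136 mg tenofovir) or 200,000 µg FTC.  With amounts in
µg and volumes in L, the plasma observable A₂/(V_c/F) is in µg/L ≡ ng/mL —
the assay unit — and the shipped CL/F values imply a daily TFV exposure of
dose/CL ≈ 96 µg·day/L ≈ 2.3 µg·h/mL, in the range typically reported for
300 mg TDF.  No lag time is modelled.

**Intracellular anabolite.** The plasma concentration stimulates formation
of TFV-DP/FTC-TP without mass transfer (plasma is "exposure", the cell is
"response"; the ng/mL → fmol/10⁶ cells conversion is folded into K_f).
Formation is first-order in plasma concentration but attenuated by a virtual
saturation compartment A₅ via 1/(1 + A₅/SC₅₀): A₅ integrates recent
exposure (input K_f·C, output at the plasma elimination rate CL/V_c, the
same K_f and CL/V_c reused to avoid over-parameterization), so sustained
high plasma levels progressively slow formation.  SC₅₀ therefore carries
plasma-concentration units (ng/mL).  Elimination is biphasic through a
recycle compartment A₆: exchange rates R·K_el on both arms and net central
loss (1−R)·K_el.  The recycle pool is a mathematical description of
re-phosphorylation or a deep/slow compartment, not a physiological
cell-trafficking model.

**dNTP pool.** Each linked dNTP (dATP and dGTP for the deoxypurine analog
TFV; dCTP and TTP for the deoxypyrimidine analog FTC) follows an
indirect-response model: zero-order production K⁰_in = R₀·K_out inhibited by
an E_max function of the anabolite level, first-order loss K_out.  E_max and
K_out are fixed to 1 (identifiability at this sample size), so R₀ is both
the baseline and the production rate in fmol/10⁶ cells/day, and the system
relaxes on a ~1-day time scale.  The transient dGTP effect is waned by the
factor 1/(1 + t^γ) multiplying the whole inhibition term, with t = days
since the subject's first dose (factor 1 at t = 0).  This is the minimal
reading of the published simplification; the waning clock is anchored
per-subject at the first dose, which coincides with study day 0 here.

## Parameters

Typical values, covariate coefficients, interindividual variances (ω²),
and residual variances (σ²) ship in `src/icpkpd/data/*.yaml` and mirror the
published population estimates.  Points worth noting:

- The recycling fraction is stored as a fraction (0.0582, 0.16), not the
  printed percent.
- The IIV "estimate" column is interpreted as ω² on the exponential scale,
  with the printed %CV equal to 100·√ω² (0.288 → 53.7%), the pharmacometric
  reporting convention; the alternative CV = √(exp(ω²)−1) does not reproduce
  the printed pairs.
- The dGTP residual variance cell is blank in the published table; it is
  reconstructed as σ² = 0.267 from the printed 51.7 %CV under the same
  convention (consistent with its printed confidence interval).
- η draws are independent across parameters (no covariance matrix is
  published) and residual errors are exponential (plasma, dNTPs) or
  proportional (anabolites).  Proportional draws below zero are clipped to
  zero and flagged; with the shipped σ² this is vanishingly rare.

## Numerical choices

The ODE system is stiff (K_a up to 80/day against terminal slopes of
~0.012/day), so integration uses LSODA with rtol 1e-8 / atol 1e-10, fixed so
that simulation-derived quantities are reproducible across runs.
Integration restarts at every dose event; samples falling exactly on a dose
time take the pre-dose (left-limit) value.  Solver-level negative
excursions beyond tolerance abort with an error; smaller ones are clipped
to zero on output.

Estimation minimizes residuals on the error-model scale (log residuals for
exponential streams, relative residuals for proportional ones) with
positive parameters on the log scale and R on the logit scale.  The
finite-difference step for Jacobians is 1e-4 — well above the ODE solver's
noise floor, which otherwise corrupts the trust-region steps.  Multi-start
(5 jittered initial vectors, seeded) guards against local minima; a
parameter whose Jacobian column norm sits at the solver-noise floor is
reported as unidentifiable and the fit flagged non-converged rather than
returning a number.  The reported objective is the least-squares surrogate
n·log(RSS/n), used only for likelihood-ratio threshold arithmetic
(forward inclusion at ΔOFV ≤ −6.64, backward retention at ΔOFV > 10.8).
Full FOCEI-style marginal-likelihood estimation of ω²/σ² is out of scope;
the estimation surface is typical-value recovery plus an optional
per-subject MAP step given ω².

The operational half-life search evaluates the accumulation ratio on a
coarse τ grid (1–9 days for TFV-DP, 0.2–2.5 days for FTC-TP, extended
downward when the crossing lies below the grid), then refines the ratio = 2
crossing by Brent bisection so the result is grid-independent.  Cmax/Cmin
are read from 400-point samplings of the first and last of 50 dosing
intervals.  dNTP reduction summaries are read at the steady-state trough
(24 h after the 30th daily dose); reading at the 8-h sample instead moves
the figures by one to two percentage points, which is why the published
medians are bracketed by ranges rather than matched as points.

## Synthetic trials: what they emulate and what they do not

The generator reproduces the design skeleton of an intensive
first-dose-to-steady-state study: an HIV-negative arm (daily dosing for 30
days; rich sampling at 1, 2, 4, 8, 24 h on days 1 and 30; pre-dose/2 h/8 h
on days 3, 7, 20; single washout samples on days 35, 45, 60) and an
HIV-positive arm (60 dosing days, day-60 visit); dNTPs at baseline, the
day-1 rich times, and 8 h post-dose at later visits.  Pre-dose samples are
taken at trough (24 h after the previous dose).  Per-sample assay LLOQs
(10 ng/mL plasma; 2.5 fmol/sample TFV-DP; 0.1 pmol/sample FTC-TP;
50 fmol/sample dNTPs) are converted to per-10⁶-cell thresholds through a
lognormal cells-per-sample draw (median 5×10⁶, CV 50%); values below
threshold are flagged BLQ and carry no numeric value, and all downstream
analysis treats them as missing.

Not emulated: dropout (beyond optional truncation), the efavirenz
co-medication of the HIV-positive arm, inter-occasion variability,
correlated random effects, assay batch effects, and any intracellular
TFV-DP/FTC-TP interaction (the drugs are always co-dosed, so the data could
not identify one).  Passing recovery and calibration tests on these
synthetic trials therefore demonstrates internal consistency of the
implementation, not that the estimation scheme would reproduce the
published estimates from the real study data.

The predictive check simulates ≥100 replicate trials under the dataset's
own design (arm sizes and covariates read from the table), pools replicate
observations per (stream, time point), and reports the fraction of observed
non-BLQ values outside the pooled 90% band (acceptable below 15%,
well-calibrated near 10%).  LLOQ censoring is not re-applied inside the
replicates; since observed BLQ rows are excluded from the coverage count,
this only matters for streams observed near the LLOQ.

## On-demand PrEP simulation

Event-driven dosing around a coitus event at t = 0: a double dose (two
tablets taken together — the natural reading of "two tablets" pre-coitus)
at 2–24 h before, single doses at +24 h and +48 h, followed for 7 days on a
0.1-day grid augmented with 10⁻⁴, 10⁻³, 10⁻² days after the first dose.
Virtual subjects are HIV-negative with the study's sex mix (67.5% male).
Ratios are computed pointwise as A₄/A₇ — both in fmol/10⁶ cells, so the
molar ratio is dimensionless — using the subject's own drug-perturbed dNTP
level in the denominator (drug concentrations dominate the ratio; the dNTP
dip contributes little).  Exceedance percentages are evaluated exactly at
t = 0 ("at the time of coitus").

## Known limitations and discrepancies

- The published FTC-TP phase half-lives (8.8 h / 76.8 h) cannot be
  recovered from the rounded published K_el and R (eigenvalues give
  10.1 h / 79.6 h); the slope windows behind the printed values are
  unstated.  The eigenvalue results are reported as-is; no window tuning is
  attempted.  These quantities are excluded from the reproduction checks.
- The same rounding propagates into the FTC-TP operational half-life under
  the Cmax,ss:Cmax,fd = 2 criterion: the published 4.8 h (equal to the
  smallest τ in the published search grid) would require the accumulation
  ratio to reach 2 at τ = 0.2 days, whereas simulation from the shipped
  parameters gives ≈2.5 there and a crossing near 14 h.  This holds under
  both readings of the first-dose Cmax (max over the first dosing interval,
  or global single-dose max).  The computed value is reported and the
  corresponding check left failing by design, documenting the discrepancy.
- The Cmax,ss:Cmin,ss FTC-TP operational half-life lands at 31.6 h against
  the published 33 h (4.3%), inside the 10% the τ-interpolation supports.
- Pooled NLS typical-value estimation is a deliberate simplification of the
  published FOCEI analysis; OFV values are not comparable across the two
  objectives, only ΔOFV threshold logic is shared.
- The baseline shrinkage estimator applies the residual random effect with
  its exponent scaled by ω²/(ω²+σ²), exactly as published, including the
  unusual residual-scaled exponent; no reinterpretation is attempted.
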