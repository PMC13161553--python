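# Methods

This note documents the statistical procedures, numerical conventions and
design choices behind `feedenergy`. All energies are kcal/kg of dry matter
(DM) unless stated; inclusions are % of diet DM.

## Balance arithmetic and ingredient methods

Diet energies follow the total-collection identities `DE_d = (GEI−GEO)/DMI`
and `ME_d = (GEI−GEO−GEU)/DMI`. Records are validated on construction:
`DMI > 0`, `0 ≤ GEO < GEI`, `0 ≤ GEU < GEI−GEO`; violations raise typed
errors naming the pig. Replicates are aggregated by computing per-pig
energies first and averaging the concentrations; digestibility
(`DE_d/GE_d`) and metabolizability (`ME_d/GE_d`) coefficients are ratios of
the means. CVs are sample CVs (ddof = 1). When a source table prints only
per-diet means, each row is treated as a single pseudo-observation and
flagged as such (`BalanceObservation.pseudo`); replicate statistics are then
unavailable by construction.

The direct method (`DE_ti = GE_ti·DE_d/GE_d`) requires the test ingredient
at ≥ 90% of diet DM and refuses otherwise, directing the caller to the
substitution method. Substitution uses
`D_ti = D_cd + (D_td − D_cd)/P_ti` applied separately to digestibility and
metabolizability coefficients, with
`P_ti = (x_ti/100)·GE_ti/GE_d(test)`. The analyzed test-diet GE is used as
the denominator when available (it is what proximate analysis reports),
falling back to the measured `GEI/DMI`. The basal coefficients come from
the near-pure corn diet of the study design — no separate basal diet
exists, and corn is the ingredient the test feeds displace. The identity is
algebraically invertible (`D_td = D_cd + (D_ti−D_cd)·P_ti`), which the test
suite checks to machine precision; with noise-free inputs the whole chain
is exact.

When per-pig records exist, ingredient energies can also be computed per
pig against the basal treatment mean and then averaged. Both paths are
provided because published tables are reproducible only to a few kcal/kg
either way; the per-pig path additionally yields ingredient-level replicate
CVs.

Outlier screening uses Tukey fences, `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`, with
median-inclusive Tukey hinges (for odd n the median belongs to both
halves). The inclusive convention is deliberate: the exclusive variant
fails to flag gross outliers in small samples (for `{1,2,3,4,100}` its Q3
is 52). Samples with fewer than four values skip the screen with a
warning.

## In vitro digestible energy

`IVDE = ((GE_t − GE_r) + GE_e)/W_t`, where the enzyme blank `GE_e` is added
back so enzyme-derived residue does not count against the sample. The blank
is the batch mean (one blank per digestion batch). Tube-level sample energy
is derived as `W_t` × the ingredient's GE concentration when not separately
measured. IVDE is homogeneous of degree zero in the tube quantities
(scaling all four leaves it unchanged), non-decreasing in `GE_e` and
non-increasing in `GE_r` — both are property-tested. A residue exceeding
sample + blank energy yields a warning (negative digestibility) but still
returns the value. Replicate CVs above 5% are logged as protocol anomalies
because the assay's repeatability (CV ≲ 1.4%) is its selling point.

## Calibration

`LinearCalibration` is a scikit-learn-style estimator (get_params/
set_params, fitted attributes with trailing underscores, `fit`/`predict`/
`score`) wrapping an ordinary least-squares fit of DE or ME on IVDE.
Stored diagnostics: slope and intercept with their OLS standard errors,
`R² = 1 − SSE/SST`, residual standard deviation `RSD = sqrt(SSE/(n−2))`,
the predictor mean and corrected sum of squares `S_xx`, and `df = n−2`.
Fits require n ≥ 3 and a non-constant predictor; two points give an exact
line with zero residual degrees of freedom and are rejected.

Intervals are **mean-response confidence intervals**,

    yhat ± t(1−α/2, n−2) · RSD · sqrt(1/n + (x0 − x̄)²/S_xx),

not prediction intervals. This is the interval appropriate for reporting an
ingredient's expected energy value from the calibration (and it is the one
that back-calculates to the published interval half-widths; a prediction
interval would be roughly four times wider at this RSD).

Slope and intercept are tested against reference values (1 and 0 for
identity-line agreement) by two-sided t-tests with OLS standard errors. An
(almost) exact fit leaves only rounding noise in the standard errors, so
when RSD is at floating-point scale the tests short-circuit: p = 1 if the
hypothesized value is reproduced, 0 otherwise. Two calibrations are
compared by pooling their training pairs in one OLS with a group indicator
and group×predictor interaction; the interaction term tests slope equality,
the indicator intercept equality. The original analysis used an
unspecified mixed-model formulation for these tests, so only the
significance direction — not the exact p-values — should be compared across
implementations.

## Additivity validation

Calculated diet energies are DM-inclusion-weighted sums of ingredient
values with mineral/vitamin supplements (dicalcium phosphate, limestone,
salt, premix) contributing zero — the convention that reproduces published
calculated values exactly. Predicted diet energies push each ingredient's
IVDE through the calibration first, then take the same weighted sum (DM
weighting, not energy weighting). Agreement is quantified three ways:

- per-diet one-sample t-tests of replicate determinations against the
  calculated/predicted reference (df = n−1);
- an agreement regression of comparator on determined values whose slope
  and intercept are tested against 1 and 0, with verdict "additive" when
  neither rejects at α = 0.05;
- the average relative difference,
  `ARD = 100·sqrt(Σ(det−pred)²/n)/mean(det)`, a root-mean-square statistic
  relative to the determined mean. The source typesets this formula
  corruptly; the RMS reading is adopted because it uniquely reproduces both
  published values (2.08% for DE, 1.62% for ME), whereas a mean-absolute
  reading gives 1.63%. ARD is scale-invariant and zero iff the vectors are
  equal.

## Synthetic studies

The generator emulates the bioassay's study conditions; its defaults are
the design it supports and are not tuned per run:

| parameter | default | meaning |
|---|---|---|
| `n_ingredients` | 20 (6 cereal / 11 protein / 3 bran) | panel size and class mix |
| `calib_slope`, `calib_intercept` | 1.0, −180 | true line IVDE = DE − 180 (the observed DE = 1.001·IVDE + 180, inverted) |
| class `ivde_offset` | 0 / −280 / −120 kcal/kg | class bias: in vitro under-captures hindgut fermentation of protein meals and brans |
| `ivde_jitter_sd` | 100 kcal/kg | ingredient idiosyncrasy around the line |
| `me_de_ratio_range` | 0.90–0.98 | ME:DE of ingredients |
| `invivo_cv_range` | 0.7–6.5% | ingredient-level DE replicate CV |
| `invitro_cv_range` | 0.1–1.4% | tube replicate CV |
| design | 2 batches × 3 periods, 1 pig/diet/cell | Youden-square, 6 replicates/diet |
| `dmi_fraction`, `initial_bw` | 4%, 37.3 ± 4.7 kg | feed intake rule |

Ingredient GE and digestibility are drawn from class envelopes (cereals
≈ 4,300–4,500 kcal/kg and 0.86–0.94; protein feeds 4,550–5,750 and
0.58–0.95; brans 4,100–5,100 and 0.55–0.82), matching the spread of common
Chinese pig-feed ingredients. Diet truths follow exact additivity of
energy, so noiseless studies recover every quantity to < 0.1 kcal/kg — the
end-to-end identity test.

Noise is multiplicative mean-one log-normal on the excreta energies
(energies are positive; CVs are quoted relatively). The fecal-output CV is
back-calculated from a per-diet target so that the *ingredient-level* DE CV
recovered downstream lands in `invivo_cv_range`: the substitution method
amplifies diet-level noise by `1/P_ti`, so substitution diets receive a
target shrunk by `x_ti·DE_ti/DE_td`. Urinary output carries a fixed 10%
relative noise (its absolute contribution is small). Truncation guards
(`GEO ≤ 0.95·GEI`, `GEU ≤ 0.95·(GEI−GEO)`) keep records inside the balance
invariants; at configured noise levels they essentially never bind.
In vitro tubes back-compute the residue energy from the true IVDE plus
replicate noise, which makes the forward computation exact by construction
and renders IVDE invariant to the assumed blank energy.

What the generator does **not** emulate: pig, period and batch random
effects (unreported in the source; the layout is generated but the noise is
i.i.d. across cells), feed refusals, marker-based collection-window errors,
diet palatability effects on intake, and any digestion kinetics. Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated noise model, not robustness to structured animal variation.

## Numerical conventions and limitations

- Energies are reported rounded to whole kcal/kg and ratios to two
  decimals, matching bioassay display conventions; internal precision is
  always full.
- Sample CVs at n = 6 are volatile (the sampling CV of a CV is ≈ 32%), so
  replicate-CV assertions in the tests use bands derived from Monte-Carlo
  oracles rather than point targets.
- The packaged fixtures print per-diet means, so the fixture pipeline runs
  the single-observation path; published per-pig means are reproduced to
  within ±5 kcal/kg (rounding of DMI to 3 decimals and energies to
  integers).
- Problem sizes in the test suite (20-ingredient panels, 2,000-replicate
  coverage experiments, ≤ 1,000-trial Monte-Carlo oracles) are chosen so
  the whole suite runs in seconds while keeping binomial/chi-square
  sampling error well inside the asserted bands.
- No net-energy (NE) system, nitrogen balance, marker-recovery modeling, or
  multivariate composition-based prediction equations are included.
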