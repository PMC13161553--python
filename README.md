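# feedenergy

Available-energy evaluation of feed ingredients for growing pigs: in vivo
digestible energy (DE) and metabolizable energy (ME) from total-collection
balance trials, in vitro digestible energy (IVDE) from enzyme-blank-corrected
digestion tubes, linear calibration of DE/ME on IVDE with mean-response
confidence intervals, and validation of energy *additivity* in mixed diets.

It is written for animal-nutrition researchers who run (or simulate) energy
bioassays and want the complete calculation chain — balance arithmetic,
ingredient-level direct/substitution methods, calibration, and agreement
statistics — as tested, composable Python instead of spreadsheet formulas.

## The model

Diet-level energies come from the classic balance identities (all energies
kcal/kg DM; GEI/GEO/GEU are daily gross-energy intake and fecal/urinary
outputs in kcal/d, DMI the dry-matter intake in kg/d):

    DE_d = (GEI − GEO) / DMI
    ME_d = (GEI − GEO − GEU) / DMI

Cereals that can be fed nearly alone get ingredient values by the **direct
method**, `DE_ti = GE_ti · DE_d/GE_d`. Ingredients that cannot (protein
meals, brans) are evaluated by the **substitution method** against a corn
basal diet:

    D_ti = D_cd + (D_td − D_cd) / P_ti,     DE_ti = GE_ti · D_ti

where the `D` are energy digestibility (DE:GE) or metabolizability (ME:GE)
coefficients of the test ingredient, basal diet and test diet, and `P_ti` is
the test ingredient's share of dietary energy.

The in vitro assay digests `W_t` kg DM of sample per tube and measures the
residue energy, corrected by an enzyme blank:

    IVDE = ((GE_t − GE_r) + GE_e) / W_t

In vivo values are then calibrated on IVDE by ordinary least squares,
`DE = a·IVDE + b`, with 95% confidence intervals for the mean response at a
new ingredient's IVDE. Additivity of the resulting values is checked in
mixed diets by DM-inclusion-weighted sums (mineral/vitamin supplements count
as zero energy), per-diet one-sample t-tests, agreement regressions tested
against the identity line, and the average relative difference

    ARD = 100 · sqrt( Σ (determined − predicted)² / n ) / mean(determined).

A synthetic-study generator (`feedenergy.simulate`) produces complete
studies — ingredient panels with known true energies, a 2-batch × 3-period
Youden-square balance trial with six replicate pigs per diet, and replicated
digestion tubes — so every stage can be verified against generator truth.

## Worked example

The packaged fixtures carry a published 20-ingredient panel. Fitting the DE
calibration and predicting corn's DE from its IVDE of 3,969 kcal/kg DM:

```python
import feedenergy as fe

panel = fe.load_fixture("table5")
cal = fe.fit_calibration(list(zip(panel["ivde"], panel["de"])), response="DE")
print(f"DE = {cal.slope_:.3f} x IVDE + {cal.intercept_:.0f} "
      f"(R2 = {cal.r2_:.2f}, RSD = {cal.rsd_:.0f} kcal/kg DM)")
yhat, lo, hi = fe.predict_with_ci(cal, 3969.0)
print(f"corn: predicted DE = {yhat:.0f} kcal/kg DM (95% CI {lo:.0f} to {hi:.0f})")
```

prints

```
DE = 1.001 x IVDE + 180 (R2 = 0.85, RSD = 310 kcal/kg DM)
corn: predicted DE = 4155 kcal/kg DM (95% CI 3984 to 4326)
```

i.e. the in vitro assay tracks in vivo DE essentially one-to-one (slope
≈ 1.0), explains 85% of the between-ingredient variance, and predicts corn's
DE with a ±171 kcal/kg mean-response interval that comfortably covers the in
vivo value of 3,986.

The same stages are available from a shell:

```sh
feedenergy report --out-dir out            # full fixture pipeline
feedenergy simulate --seed 1 --out-dir sim # synthetic study + recovery report
feedenergy predict --ivde 3969             # single-ingredient prediction
```

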