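# pipn

Quantitative tooling for studying **paclitaxel-induced peripheral
neuropathy (PIPN)** and candidate protective co-medications
(α1-adrenergic receptor antagonists such as tamsulosin and doxazosin).
The package implements the two analytic arms such a study needs, plus
synthetic-data generators with known ground truth so every statistic can be
validated end to end:

1. **Pharmacovigilance disproportionality analysis** on FAERS-style
   spontaneous adverse-event reports (case/non-case design within the
   paclitaxel stratum).
2. **Preclinical quantification**: 50% mechanical withdrawal thresholds
   from von Frey up–down (Dixon staircase) sessions, and sciatic-nerve
   fiber morphometry (circularity, g-ratio, myelin thickness) from polygon
   geometry or label masks.

It is aimed at pharmacoepidemiologists and preclinical pain researchers who
want an auditable, scriptable version of analyses usually spread across
database front-ends, spreadsheets and ImageJ.

## The statistics

Within the stratum of reports listing the target drug, a report is a
**case** if it lists any PIPN preferred term (peripheral neuropathy,
peripheral sensory neuropathy, peripheral sensorimotor neuropathy) and
**exposed** if it lists the concomitant drug (or any member of a drug
class).  With cells n11 (exposed cases), n12 (exposed non-cases), n21, n22:

```
ROR    = (n11/n21) / (n12/n22) = n11·n22 / (n12·n21)
95% CI = exp[ ln ROR ± 1.96·√(1/n11 + 1/n12 + 1/n21 + 1/n22) ]
```

Association is tested with the 1-df Pearson chi-squared statistic, with
Yates' continuity correction when any cell count is below 5.  Zero cells
leave the ROR undefined (explicit error) unless the Haldane–Anscombe +0.5
correction is requested, and the correction is always flagged in the
output.  A count-inversion oracle (`invert_counts`) enumerates the 2×2
tables compatible with a published rounded ROR/CI and margins — useful for
auditing analyses whose cell counts were never printed.

Withdrawal thresholds use the up–down estimator `10^(X_f + k·δ)` where
`X_f` is the final filament's log10 force, `δ` the series' mean log
spacing, and `k` a response-pattern offset (tabulated maximum-likelihood
values under Dixon's probit model, shipped in `data/k_table.json`).
Morphometry uses exact polygon measures: circularity `4πA/P²`, g-ratio as
the ratio of equivalent-circle diameters, myelin thickness as half the
diameter difference.

## Worked example

Six paclitaxel reports, two also listing tamsulosin; one report in each
exposure group is a PIPN case (`examples/toy.yaml` ships this fixture):

```bash
pipn run --config examples/toy.yaml --out out_toy
```

`out_toy/signals.csv`:

```
group,n11,n12,n21,n22,ror,ci_low,ci_high,chi2,p_value,yates_applied,...
tamsulosin,1,1,1,3,3,0.0837564787,107.4543742,0,1,True,...
```

Reading: exposed odds 1/1 vs unexposed odds 1/3 give ROR = 3 with a CI of
0.08–107 (four reports per arm carry almost no information), and the
Yates-corrected chi-squared is floored at 0 (p = 1).

A full synthetic run (all three arms, seed 17, true odds multiplier 0.5 for
the exposure — i.e. the concomitant drug halves the odds of a PIPN report):

```bash
pipn run --config examples/demo.yaml --out out_demo
```

prints, among others, `signals.csv` with

```
tamsulosin,19,1025,407,8585,0.3909989812,0.2457062428,0.6222072407,...
```

— the estimated ROR 0.39 (95% CI 0.25–0.62) excludes 1, recovering the
generating multiplier 0.5 to within sampling noise — and a morphometry
summary in which the degenerated group shows lower circularity (0.940 vs
0.999), higher g-ratio (0.714 vs 0.590) and thinner myelin (1.15 µm vs
1.66 µm) than controls, the expected histological pattern.  Identical
config + seed reproduces every output byte for byte.

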