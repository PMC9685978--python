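# mrscreen

Two-sample summary-data Mendelian randomisation (MR) screening in Python:
instrument selection and harmonisation for GWAS summary statistics,
pleiotropy-robust causal estimators, multivariable adjustment models,
Bayesian model averaging for exposure ranking, and a seeded synthetic-data
generator with known ground truth.

## Who this is for

Genetic epidemiologists screening many candidate exposures (for example, a
panel of circulating biomarkers) against one or more disease outcomes using
only published GWAS summary statistics — per-variant effect sizes, standard
errors and p-values from an exposure GWAS and a non-overlapping outcome
GWAS. The package runs the whole screen end to end and also exposes each
step as a statsmodels-style model object for interactive use.

## The statistics

For variant *j*, let β̂<sub>Xj</sub> (SE σ<sub>Xj</sub>) be its effect on a
standardised exposure and β̂<sub>Yj</sub> (SE σ<sub>Yj</sub>) its effect on
the outcome log-odds. If *j* is a valid instrument, β<sub>Yj</sub> = θ
β<sub>Xj</sub> with θ the causal effect (log-odds per SD; reported as
OR = e^θ).

- **Wald ratio** — θ̂<sub>j</sub> = β̂<sub>Yj</sub>/β̂<sub>Xj</sub>, used
  when only one instrument survives selection.
- **IVW** — fixed-effect meta-analysis of the Wald ratios weighted by
  σ<sub>Yj</sub><sup>−2</sup>; the primary estimator of the screen,
  equivalent to weighted regression of β̂<sub>Y</sub> on β̂<sub>X</sub>
  through the origin.
- **MR-Egger** — adds an intercept that absorbs directional pleiotropy
  under the InSIDE assumption; the intercept test flags pleiotropy.
- **Weighted median** — consistent while ≥50% of the weight comes from
  valid instruments; bootstrap SE.
- **MR-PRESSO** — simulation-based global heterogeneity test, per-SNP
  outlier flagging, outlier-corrected IVW, and a distortion test.
- **Multivariable IVW** — direct effects of K exposures jointly, for
  adjustment models (e.g. lipid panels, or anthropometric co-exposures).
- **MR-BMA** — Bayesian model averaging over all 2^K − 1 exposure subsets;
  ranks exposures by marginal inclusion probability (MIP) with
  model-averaged causal effects (MACE) and permutation p-values.

Benjamini–Hochberg FDR is applied across exposures within each outcome.
`docs/methods.md` has the full model descriptions, defaults and caveats.

## Worked example

The package ships a fixed 5-SNP panel with concordant alleles and
genome-wide-significant exposure effects:

```python
from mrscreen import (fixture_small, select_instruments, harmonise,
                      ivw, egger, f_statistics)

exposure, outcome = fixture_small()
iv = select_instruments(exposure)      # p < 5e-8, LD clumping
h = harmonise(iv, outcome)             # align effect alleles
f = f_statistics(h)
print(f"F range: {f['min']:.0f} to {f['max']:.0f}")
print(ivw(h).summary())
print(egger(h).summary())
```

```
F range: 118 to 681
ivw MR estimate (5 SNPs)
  theta  =  0.1015  (SE 0.0227)
  95% CI = [ 0.0571,  0.1459]
  OR/SD  = 1.11  (1.06, 1.16)
  p      = 7.47e-06
egger MR estimate (5 SNPs)
  theta  =  0.0958  (SE 0.0765)
  95% CI = [-0.1477,  0.3393]
  OR/SD  = 1.10  (0.86, 1.40)
  p      = 0.299
  intercept =  0.00025 (SE 0.00317, p = 0.943)
```

Reading it: every instrument is strong (F ≫ 10). The IVW estimate says a
1-SD increase in the genetically predicted exposure raises the outcome odds
by 11% (OR 1.11, 95% CI 1.06–1.16). The Egger slope agrees in direction
with a wider interval, and its intercept is indistinguishable from zero —
no evidence of directional pleiotropy on this panel.

A full screen runs from a YAML config on the command line:

```sh
mrscreen simulate --manifest manifest.yaml --out-dir simulated/
mrscreen run --config screen.yaml
mrscreen uvmr simulated/exposure_0.tsv simulated/outcome.tsv
```

or programmatically via `run_screen`, `run_bidirectional`, `run_mvmr_preset`
and `run_ranking`, which return tidy pandas reports and render deterministic
TSV/markdown outputs.

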