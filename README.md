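# grmsim

Simulation and diagnostics toolkit for **three-category graded response
models**: calibrated synthetic response data with known structure, marginal
maximum likelihood estimation (2PL/1PL), Yen's Q3 local-independence
screening with item-exclusion strategies, polychoric
dimensionality/reliability diagnostics, and severity-banded maximum-utility
item selection.

## The problem

Rehabilitation robots rate every training movement a patient performs on a
three-point quality scale (0 = too hard / heavy compensation, 1 = adequate,
2 = too easy). With 71 candidate training items, therapists need an
*objective* way to (i) check that one latent severity dimension θ explains
the ratings, (ii) prune item pairs that violate local independence (items
that are redundant given θ), and (iii) pick a short battery — say 7 items —
matched to a patient's severity band. `grmsim` implements that entire study
as a reproducible pipeline on simulated data whose ground truth is known, so
every step (parameter recovery, dependence detection, selection) can be
validated end to end.

## The model

For item *j* with discrimination *a<sub>j</sub>* and ordered thresholds
*b<sub>j1</sub> < b<sub>j2</sub>*:

```
p*_jc(θ) = 1 / (1 + exp[−D·a_j·(θ − b_jc)])          c = 1, 2
p_0 = 1 − p*_1,   p_1 = p*_1 − p*_2,   p_2 = p*_2
I_j(θ) = D²a_j² Σ_c [p*_c q*_c − p*_{c+1} q*_{c+1}]² / p_c(θ)
```

Item parameters are estimated by MML-EM under a standard normal prior;
abilities by EAP. Local dependence between items *j, k* is screened with
Yen's Q3 — the Pearson correlation of residuals *x − E[x|θ̂]* — flagging
pairs with |Q3| > 0.2. See `docs/methods.md` for the full account.

## Worked example

```python
from grmsim import (GeneratorConfig, ModelSpec, generate_dataset, fit_matrix,
                    q3_statistic, select_exclusions, rank_items_in_band,
                    SeverityBand)
import numpy as np

matrix, truth = generate_dataset(GeneratorConfig(seed=1))
print(matrix.n_cases, "cases x", matrix.n_items, "items")

fit = fit_matrix(matrix, ModelSpec())          # 2PL by MML-EM
theta = fit.predict(matrix.values)             # EAP abilities
print("mean a  %.3f   mean b1 %.3f   mean b2 %.3f"
      % (fit.discrimination_.mean(), *fit.thresholds_.mean(axis=0)))
print("theta: mean %.4f  sd %.4f" % (theta.mean(), np.std(theta, ddof=1)))

q3 = q3_statistic(matrix.values, fit, theta, 0.2, item_ids=matrix.item_ids)
excluded = select_exclusions(q3, fit, "max_cat1_prob")
print(len(q3.flagged_pairs), "flagged pairs ->", 71 - len(excluded),
      "items kept")

pruned = matrix.select_items([i for i in matrix.item_ids if i not in excluded])
refit = fit_matrix(pruned, ModelSpec())
severe = rank_items_in_band(refit.items_frame(),
                            SeverityBand("severe", -2.0, -0.5), "cat1_prob")
print("severe-band battery:", sorted(severe.selected_item_ids))
```

Output:

```
298 cases x 71 items
mean a  2.874   mean b1 -0.469   mean b2 0.462
theta: mean -0.0001  sd 0.9974
16 flagged pairs -> 58 items kept
severe-band battery: [1, 2, 3, 4, 6, 8, 9]
```

Reading this: the fitted discriminations average ≈ 2.9 and the two threshold
sets average ≈ ∓0.44, recovering the generator's calibration; EAP abilities
are centred with sd ≈ 1. The Q3 screen catches all ten dependence-injected
pairs (the extra flags are the n = 300 noise floor of a residual
correlation — see `docs/methods.md`), and the category-1 criterion picks the
easiest items for the severe band, as it should when difficulty rises with
item ID.

The same study runs from the shell:

```bash
grmsim run-all --seed 1 --out run1/      # full pipeline, report.json + CSVs
grmsim simulate --seed 7 --out resp.csv  # just the synthetic data
grmsim fit --in resp.csv --model 2pl     # just the model fit
```

## Layout

| module | contents |
|---|---|
| `grmsim.simulate` | generator: true parameters/abilities, copula-coupled responses, degenerate-case elimination, descriptives |
| `grmsim.grm` | GRM probabilities/information, `GradedResponseModel` (MML-EM, EAP, AIC/BIC) |
| `grmsim.dimensionality` | polychoric correlations, parallel analysis, Cronbach's α |
| `grmsim.local_independence` | Q3, exclusion strategies, `Q3Screener`, strategy × model comparison |
| `grmsim.selection` | severity bands, ICC/IIF/TIF curve grids, top-k ranking, criterion comparison |
| `grmsim.pipeline` / `grmsim.cli` | end-to-end orchestration and the `grmsim` command |
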