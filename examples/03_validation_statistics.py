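"""CLIA-style validation statistics on simulated score tables.

Shows the three statistical tools the validation uses: the intraclass
correlation (ICC) from a two-way random-effects variance decomposition
with a parametric-simulation 95% CI, Bonferroni-corrected Pearson
concordance, and treatment-bin accuracy concordance with simulated manual
readers.
"""
import numpy as np

import tissuescore as ts
from tissuescore.validation import icc_precision, icc_simulation_ci

rng = np.random.default_rng(0)

# --- precision: 20 samples read on 3 days, most variance between samples
table = (rng.normal(40, 25, (20, 1))          # sample effects
         + rng.normal(0, 1.5, (1, 3))         # day effects
         + rng.normal(0, 1.5, (20, 3)))       # residual
res = icc_simulation_ci(icc_precision(table), n_sim=1000, seed=1)
print(f"ICC = {res.icc:.3f}  95% CI ({res.ci95[0]:.3f}, {res.ci95[1]:.3f})"
      f"  reliability: {res.reliability}  pass(>=0.6): {res.passed}")
print("variance proportions:",
      {k: round(v, 3) for k, v in res.proportions.items()})

# --- concordance: digital vs three simulated readers, Bonferroni 0.05/3
true_tps = rng.uniform(0, 95, 66)
reads = ts.generate_reader_scores(
    true_tps, ts.SimulatedReaderModel(bias=0, between_read_sd=2,
                                      per_reader_sd=1, seed=2))
first = reads[reads.read == 0]
pairs = [(f"digital_vs_reader{r}", true_tps,
          first[first.reader == r].score.to_numpy()) for r in range(3)]
conc = ts.pearson_concordance(pairs, n_comparisons=3)
print(f"\nBonferroni-corrected alpha: {conc.alpha_reported}")
for name, r, p, sig in conc.pairs:
    print(f"  {name}: r = {r:.3f}, p = {p:.2e}, significant: {sig}")

# --- accuracy: same treatment decision (TPS >= 1%) in >= 90% of samples
frac, ok = ts.accuracy_concordance(true_tps,
                                   first[first.reader == 0].score)
print(f"\ntreatment-bin concordance: {frac:.2%}  pass(>=90%): {ok}")
# An ICC >= 0.6 (point and CI) passes precision; r with p below the
# corrected alpha passes concordance; bin agreement >= 90% passes accuracy.
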