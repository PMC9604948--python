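# morphokin

Morphokinetic analysis of time-lapse records from in-vitro embryo
production: rule-based cleavage-pattern classification, developmental
kinetics, run-level cohort statistics with pattern–outcome odds ratios, a
calibrated stochastic cohort simulator, and downstream transcript-list
operations (differential-expression gates, Venn partition, 2^−ΔΔCt).

## The problem

Time-lapse incubators image each embryo every 5 minutes, yielding for
every embryo an annotated event log: the times (hours post-fertilization)
at which it reaches each blastomere count and each post-cleavage stage
(morula, early blastocyst, blastocyst, expanded blastocyst). From such
logs, embryologists classify the first-cleavage pattern and ask whether
it predicts development:

* **normal** — first division into two equal blastomeres, subdivided into
  **synchronous** (subsequent divisions pass only through 4-, 8- and
  16-cell states) and **asynchronous** (at least one division yields 3,
  5, 6, 7, 10 or 12 blastomeres; embryos are binned by their number of
  asynchronous events into classes 1, 2, 3, 4 or 5–6);
* **abnormal** — **direct** (1 → ≥3 cells in one division), **unequal**
  (two markedly different-sized blastomeres) or **reverse** (2 → 1 cells
  through the first division); an embryo can show more than one.

The association between pattern and blastocyst formation is the saturated
one-factor logistic model: with outcome counts $a/n_1$ in a pattern group
and $c/n_0$ in the reference (synchronous) group, the fitted odds ratio
is the cross-product ratio

$$\mathrm{OR} = \frac{a\,d}{b\,c}, \qquad
\log \mathrm{OR} \pm 1.96\sqrt{\tfrac1a+\tfrac1b+\tfrac1c+\tfrac1d}$$

with $b = n_1 - a$, $d = n_0 - c$ (Wald 95% CI; Haldane–Anscombe +0.5
when a cell is empty). Run-level proportions are reported as mean ± SEM
over IVF runs, with arcsin √p feeding the ANOVA/t pathway. Timing
comparisons use self-implemented rank tests: the Wilcoxon rank-sum test
with full permutation enumeration for pooled n ≤ 12 (normal
approximation with tie and continuity corrections otherwise) and the
tie-corrected Kruskal–Wallis H.

Because raw time-lapse datasets of this kind are rarely deposited, the
package includes a first-class simulator: each embryo draws a pattern
from cohort frequencies, realizes that pattern's defining event sequence,
and times it as *tempo × template + jitter*, where the per-embryo tempo is
lognormal with median 1 — so cohort medians reproduce the template
(29.0 / 38.7 / 51.0 h for the first three cleavages; 113.0 / 130.5 /
159.5 / 166.5 h for morula through expanded blastocyst) by construction.

## Worked example

```python
import pandas as pd
from morphokin import (SimParams, simulate_cohort, classify_cohort,
                       run_level_summary, CleavageOutcomeModel)
from morphokin.events import Stage

cohort, truth = simulate_cohort(SimParams(seed=1))   # 36 runs x 28 embryos
calls = classify_cohort(cohort)
s = run_level_summary(calls, numerator=calls["top"] == "normal")
print(f"normal: {s.pooled_numer}/{s.pooled_denom} "
      f"({s.mean_pct:.1f} +/- {s.sem_pct:.1f}%)")

outcome = pd.Series([Stage.BLASTOCYST in r.reached for r in cohort.records],
                    index=calls.index)
res = CleavageOutcomeModel.from_calls(
    calls, outcome, reference="synchronous",
    levels=["synchronous", "asynchronous", "direct", "unequal", "reverse"]).fit()
print(res.summary())
```

prints

```
normal: 699/1008 (69.3 +/- 1.8%)
Pattern-outcome association (saturated logistic / cross-product ORs)
reference level: synchronous
chi-square (4 df): 66.1526, p = 1.471e-13
level                   n  events       OR            95% CI         p
synchronous           441      75  1 (ref)
asynchronous          258      82    2.274    [1.585, 3.262]  8.26e-06
direct                196      13    0.347    [0.187, 0.641]  0.000735
unequal                93       5    0.277    [0.109, 0.706]   0.00715
reverse                18       0    0.131    [0.008, 2.201]     0.158 (HA+0.5)
```

Reading it: 699 of 1,008 simulated embryos cleaved normally (69.3 ± 1.8%
as mean ± SEM over the 36 runs). Asynchronously cleaved embryos had 2.3
times the odds of forming a blastocyst relative to synchronous ones;
direct and unequal cleavage markedly reduced the odds; no reverse-cleaved
embryo developed, so its comparison carries the +0.5 continuity flag.

The same analyses run from the shell:

```sh
morphokin simulate --seed 7 --out cohort.csv --truth truth.tsv
morphokin classify --in cohort.csv --out calls.tsv
morphokin kinetics --in cohort.csv --out kinetics.tsv
morphokin report --seed 7 --out-dir report/
morphokin de --in degs.tsv --out filtered.tsv --venn other.tsv
morphokin ddct --in ct.tsv --out folds.tsv
```

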