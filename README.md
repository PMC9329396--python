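# pairpref

Bradley–Terry analysis of forced-choice paired-comparison preference
studies — built around a sensory study in which 37 healthy volunteers
compared the taste of 8 commercial liquid thickeners (powders used to
thicken drinks in dysphagia management, products A1–A8) in 224 pairwise
tastings. The package is for anyone running or re-analyzing such panels:
it fits latent "worth" scores from win/loss judgments, tests every pairwise
contrast, reports reference-free quasi-standard errors, generates
randomized study designs, and simulates whole studies for power and
recovery experiments.

## The model

Each item *i* has a latent worth π_i > 0; in a forced choice between *i*
and *j*, item *i* is preferred with probability π_i / (π_i + π_j). With
β_i = log π_i this is a logistic model on contrasts,

    logit p_ij = β_i − β_j  ( + δ when i is tasted first ),

where δ is an optional presentation-order advantage. Only contrasts are
identifiable, so one reference item is pinned at β = 0. The package
provides:

- maximum-likelihood fitting by two independent algorithms
  (minorize–maximize on the worths, Newton–Raphson on the contrast design),
  with separation diagnostics via strong connectivity of the win digraph;
- Wald tests of every contrast (equivalently: each item once as reference);
- quasi-variances q_i minimizing Σ_{i<j} [log(q_i+q_j) − log Var(β̂_i−β̂_j)]²,
  so per-item error bars approximately support any pairwise comparison;
- a global likelihood-ratio test against the equal-worth (fair coin) null;
- a randomized incomplete design generator (no repeated combination per
  subject, coin-flip presentation order) and a full study simulator.

## Worked example

```python
import pairpref as pp

counts = pp.load_fixture_counts()      # the bundled 8-item study data
report = pp.run_analysis(counts, reference="A1")
print(report.coefficient_table().round(2))
print("ranking:", " > ".join(report.ranking()))
print("global test p =", report.global_test.p_value)
print("p(A4 vs A5) =", round(report.pairwise.p_value("A4", "A5"), 2))
```

prints

```
      beta    se  p_value  quasi_se
item
A1    0.00   NaN      NaN      0.37
A2   -2.20  0.50     0.00      0.32
A3   -1.34  0.47     0.00      0.29
A4    1.49  0.59     0.01      0.52
A5    1.19  0.53     0.02      0.47
A6   -1.60  0.49     0.00      0.31
A7   -1.75  0.49     0.00      0.31
A8   -2.52  0.52     0.00      0.34
ranking: A4 > A5 > A1 > A3 > A6 > A7 > A2 > A8
global test p = 5.574938157932046e-24
p(A4 vs A5) = 0.63
```

Read: A4 and A5 (both clear, xanthan-based thickeners) taste markedly
better than the rest — their worths are e^1.49 ≈ 4.4 and e^1.19 ≈ 3.3
times that of the reference A1 — and are statistically indistinguishable
from each other (p = 0.63), while the starch-based products rank lowest.
The same analysis is available from the shell:

```sh
pairpref reproduce --out report.json --md report.md
pairpref design --items 8 --subjects 37 --per-subject 7 --seed 1 --out design.csv
pairpref simulate --seed 1 --delta 0.13 --out records.csv
pairpref fit --records records.csv --order-effect --out fit.json
```

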