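# mammofuse

Score-level ensemble fusion for multi-classifier medical-image pipelines,
built around a **fuzzy-rank fusion rule using a modified Gompertz function**,
with weighted-average and Sugeno-integral baselines, a mammogram
preprocessing chain, evaluation statistics (per-class metrics, Cohen's kappa,
one-way ANOVA), and seeded synthetic generators so everything is testable
without any image database.

## Who this is for

Researchers combining the softmax outputs of several classifiers (e.g. CNN
backbones for three-class mammogram classification: normal / benign /
malignant) who want a dynamic, per-sample fusion rule instead of static
ensemble weights — plus the surrounding plumbing: MLO-view preprocessing
(impulse-noise removal, border cropping, orientation, pectoral-muscle
removal, resizing) and evaluation/validation statistics.

## The fusion rule

Each classifier `n` emits a softmax score vector `S^(n)` over `L` classes
(`Σ_l S_l^(n) = 1`).  Scores are mapped to **fuzzy ranks** with the
complement of a Gompertz curve,

    R_l^(n) = 1 − m·exp(−exp(n_shift − p·S_l^(n))),     defaults (m, n_shift, p) = (1, 0, 2),

a strictly decreasing transform: confident scores get low ranks, and a score
of zero still maps to the finite worst rank `1 − 1/e`.  Per classifier the
`k = 2` best-ranked classes form its top-`k` set; every other class incurs
penalties.  Two per-class sums,

    FRS_l  = Σ_n [ R_l^(n) or P^(R) ]          (fuzzy rank sum)
    CCFS_l = mean_n [ 1 − S_l^(n) or P^(CF) ]  (complementary confidence factoral sum)

are multiplied, and the fused class is `argmin_l FRS_l·CCFS_l`.  Weighted
average (argmax of a convex combination) and the Sugeno integral (max–min
aggregation against a λ-fuzzy measure) are provided as baselines.  See
`docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from mammofuse import ScoreTensor, fuzzy_rank_fusion

scores = np.array([          # 3 classifiers, 1 sample, 3 classes
    [[0.7, 0.2, 0.1]],
    [[0.5, 0.3, 0.2]],
    [[0.1, 0.6, 0.3]],
])
res = fuzzy_rank_fusion(ScoreTensor(scores))
print("FRS  ", np.round(res.frs[0], 6))
print("CCFS ", np.round(res.ccfs[0], 6))
print("fused", np.round(res.fused_score[0], 6), "->", res.fused_class[0])
```

prints

```
FRS   [1.158464 1.170885 1.686605]
CCFS  [0.6      0.633333 0.9     ]
fused [0.695079 0.741561 1.517945] -> 1
```

Classes 1 and 2 are in the top-2 set of every classifier, so their rank sums
collect three genuine ranks each, while class 3 is penalised twice; class 1
wins the argmin of `FRS × CCFS` even though classifier 3 preferred class 2 —
its two supporters rank it higher *and* score it more confidently.

The same workflow from the shell:

```bash
mammofuse simulate --seed 5 --out run/          # synthetic scores + labels
mammofuse fuse run/scores.csv --method gompertz --out run/fusion.json
# preds.csv: columns sample_id,predicted — e.g. extracted from fusion.json
mammofuse evaluate run/preds.csv --labels run/labels.csv --out run/metrics.json
mammofuse preprocess phantom.png --out run/     # filter, crop, orient, PM removal, resize
```

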