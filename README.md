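# crossband

Decoding continuous EEG band power from parcellated fast-fMRI time
series — and mapping which brain regions and networks carry the
predictive information.

## The problem

During drowsiness and sleep, occipital EEG alpha (8.5–12 Hz) and delta
(1.1–4 Hz) power track vigilance on timescales of seconds to minutes.
Fast fMRI (TR ≈ 0.38 s) samples hemodynamics quickly enough to ask the
converse question: how much of that electrophysiological fluctuation can
be read back out of regional BOLD signals alone, and from where?
`crossband` is a tested, reusable implementation of that analysis for
researchers working with simultaneous EEG–fMRI: a decoding pipeline
(multitaper band power → TR-level QC → sliding-window ridge regression
→ leave-one-subject-out evaluation) plus the downstream analyses that
localize the information (anatomical-group comparisons, single-region
maps, pairwise-benefit network clustering with gap-statistic model
selection, iterative region pruning). A synthetic-data module generates
coupled EEG–fMRI datasets with planted network structure and known
ground truth, so every stage is testable end to end without any data
download.

## The model

Each EEG power sample y_t (interpolated to TR times, rescaled to [0, 1]
per subject) is predicted from a 60-TR window of all regions' z-scored
BOLD, the sample aligned to the window's 30th TR:

    ŷ_t = b + Σ_r Σ_{τ=1..60} β_{r,τ} · x_r(t − 30 + τ)

with β fit by ridge regression (min ‖y − Xβ − b‖² + λ‖β‖²). λ is chosen
per training fold by 5-fold cross-validation over 30 log-spaced
candidates, using only the training subjects; performance is Pearson's r
between predictions and truth for a fully held-out subject, averaged
over 10 seeds. Centering the EEG sample in the fMRI window avoids
assuming any hemodynamic lag. Downstream, the pairwise *benefit*
b(i,j) = r_pair(i,j) − max(r_i, r_j) quantifies complementary vs
redundant information between regions; k-means on benefit profiles with
the gap statistic (Gap(k) ≥ Gap(k+1) − SE(k+1)) identifies networks.
See `docs/methods.md` for the full treatment.

## Worked example

`examples/02_decode_alpha.py` simulates 5 subjects × 1000 TRs on a
reduced 16-region atlas, runs the full pipeline, and prints:

```
27 artifact-free segments after QC
design: 2250 windows x 960 predictors (16 regions x 60 TRs)
  held-out sub-01: r = 0.923 (lambda = 6.77e+03)
  held-out sub-02: r = 0.913 (lambda = 5.87e+03)
  held-out sub-03: r = 0.897 (lambda = 5.86e+03)
  held-out sub-04: r = 0.904 (lambda = 6.24e+03)
  held-out sub-05: r = 0.962 (lambda = 6.86e+03)
LOSO mean held-out r = 0.920
temporal-shuffle control mean r = 0.011 (should be ~0: ...)
```

Each `r` is the correlation between the predicted and true alpha-power
time course of a subject the model never saw; the shuffle control
destroys the EEG–fMRI temporal pairing and should (and does) decode
nothing. The other examples cover simulation and on-disk layout (01),
region maps with ANOVA/Tukey and the bootstrap ordering control (03),
network recovery by pairwise-benefit clustering (04), and iterative
low-weight-region pruning (05).

A thin CLI mirrors the stages
(`crossband simulate|power|qc|train|map|cluster|prune|report`), e.g.

```
crossband simulate --seed 0 --out data/
crossband train --data data/ --band alpha --subset brainwide --out res.json
```

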