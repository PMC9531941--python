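# neurostates

Neural state segmentation of fMRI time series.

During naturalistic stimulation (watching a movie, listening to a story),
the multi-voxel activity pattern of a brain region passes through periods
of relative stability — *neural states* — separated by rapid transitions.
`neurostates` detects those transitions with a greedy state boundary
search (GSBS), selects the number of states with a t-distance criterion,
and quantifies how the resulting boundaries relate to perceived *event
boundaries* and to the boundaries of other regions: scalp-to-scalp
searchlight mapping, chance-scaled overlap statistics, consensus network
partitioning, and group-level inference. A synthetic-data generator with
planted (optionally nested) boundaries makes the whole pipeline testable
without any imaging data.

## The method in brief

**Segmentation.** For a timepoints × voxels matrix, GSBS iteratively adds
boundaries at the locations maximizing the *fit* — the mean Pearson
correlation (across voxels) between each timepoint and the mean pattern
of its state. Each iteration may place one boundary or two at once (the
two-boundary step carves a whole new state out of an existing one,
restricted to a single state); the choice between the one- and
two-boundary candidates is made by the **t-distance**

> t(k) = two-sample t statistic contrasting {corr(t₁, t₂) : same state}
> against {corr(t₁, t₂) : consecutive states},

and after every placement all boundaries are fine-tuned by ±1 TR shifts,
sweeping from the weakest boundary (smallest correlation distance between
flanking state means) to the strongest. The optimal k maximizes t(k).
Because the hemodynamic response blurs transitions, data can first be
high-pass filtered (0.008 Hz), Wiener-deconvolved with the canonical
double-gamma HRF, and averaged over participants.

**Overlap statistics.** Boundaries are compared as binary per-TR series.
With O = Σₜ Eₜ·Sₜ and the chance expectation OE = (ΣE)(ΣS)/n,

- absolute overlap OA = (O − OE) / (ΣS − OE) — 0 at chance, 1 when every
  state boundary coincides with an event boundary;
- relative overlap OR = (O − OE) / (min(ΣE, ΣS) − OE) — scaled by the
  maximum achievable overlap, symmetric for binary series.

Variants weight the marks by boundary strength or by co-occurrence across
searchlights, and boundary sets of two regions can be decomposed into
shared and unique parts.

**Networks and inference.** The pairwise OR matrix between searchlights
is clustered by consensus: repeated signed-modularity Louvain runs
(asymmetric Q\* that down-weights negative weights), a co-assignment
matrix thresholded at the random-label chance level, re-clustered until
stable; resolution γ is chosen by adjusted mutual information against a
reference parcellation. Statistics are re-computed in independent
participant subgroups and tested with an exact Wilcoxon signed-rank test,
Benjamini–Hochberg FDR, and a sign-consistency veto.

## Worked example

```python
import numpy as np
from neurostates import (SimulationConfig, generate_dataset, group_average,
                         place_boundaries, state_duration_summary,
                         events_to_series, absolute_overlap, series_from_segmentation)

cfg = SimulationConfig(n_regions=2, n_networks=2, n_subjects=20, noise_sd=1.0, seed=7)
gt, data, events = generate_dataset(cfg)

e = events_to_series(events["onset_s"], events["salience"], tr=cfg.tr, n=cfg.n_timepoints)
for rid in sorted(gt.regions):
    avg = group_average([data[(rid, s)] for s in range(cfg.n_subjects)])
    segs, curve = place_boundaries(avg, k_max=40)
    seg = next(s for s in segs if s.k == curve.optimum_k)
    med, cv = state_duration_summary(seg, cfg.tr)
    oa = absolute_overlap(e, series_from_segmentation(seg)).absolute
    print(f"region {rid}: k={seg.k} states, median duration {med:.1f} s, "
          f"IQR/median {cv:.2f}, event overlap OA={oa:.2f} "
          f"(planted k={gt.regions[rid].size + 1})")
```

prints

```
region 0: k=11 states, median duration 19.8 s, IQR/median 2.81, event overlap OA=0.18 (planted k=8)
region 1: k=15 states, median duration 27.2 s, IQR/median 0.86, event overlap OA=0.12 (planted k=15)
```

Region 1 (fast network, 15 planted states) is recovered exactly; region 0
overshoots by a few states — at this noise level the t-distance curve is
flat near its maximum and extra weak boundaries absorb residual noise, a
behaviour the group-level inference machinery is designed to handle. The
positive OA values say that more state boundaries coincide with the
planted event boundaries than chance predicts.

The same pipelines are available from the shell:

```bash
neurostates simulate --config sim.yaml --out dataset/
neurostates segment  --data dataset/subject000.nii --mask dataset/regions.nii --out seg/
neurostates overlap  --events dataset/events.tsv --boundaries seg/ --tr 2.47 --out overlap.tsv
neurostates networks --matrix overlap.pairwise.tsv --out partition.tsv
neurostates stats    --table group_metrics.tsv --out pvalues.tsv
neurostates pipeline --config sim.yaml --out run/
```

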