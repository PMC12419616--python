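# predeath

Tools for characterizing how patients' internal states evolve over the
final months of life, from nothing more than routinely collected
laboratory time series.

Clinicians and biostatisticians studying end-of-life care face a common
obstacle: single prognostic markers describe organ systems in isolation,
while the process of dying is a coordinated, heterogeneous drift across
the whole panel. `predeath` implements an interpretable machine-learning
framework for decedent cohorts — patients with a known death date and
irregular lab sampling over their last year — that turns that drift into
quantitative, comparable objects:

1. **Horizon mortality models.** For each horizon *n* ∈ {1..90} days, a
   gradient-boosted decision-tree classifier learns to distinguish the
   patient state *n* days before death (positive) from the same cohort's
   state 168 days (24 weeks) before death (negative). Including only
   patients observed at both anchors makes every dataset exactly 1:1
   balanced; performance is patient-level 5-fold cross-validated AUROC.
2. **Attribution behaviors.** Each prediction decomposes exactly into
   per-analyte Shapley contributions φ in log-odds space
   (base + Σⱼ φⱼ = margin). Restricting to correctly predicted positives,
   the signed mean attribution per analyte, scaled per horizon by the
   dominant analyte's mean (so the top trajectory touches ±1), yields each
   analyte's *importance trajectory* s_j(n) over the 90 days before death.
3. **State-space visualization.** (patient, horizon) attribution vectors
   are stacked across horizons and embedded to 2D (UMAP, euclidean,
   `n_neighbors=10`, `min_dist=0.5`), against a paired embedding of
   standardized raw values; a temporal-separation score (best |Spearman|
   between horizon and an embedding axis) quantifies whether the pre-death
   timeline is visible.
4. **Subtype stratification.** Ward-linkage hierarchical clustering of
   one-day-before-death attribution vectors (Euclidean distance, k chosen
   by silhouette with the elbow curve reported) identifies terminal
   trajectory subtypes, which are profiled by median (IQR) lab summaries,
   Kruskal–Wallis + pairwise Mann–Whitney tests with Holm correction at
   α = 0.01, and per-subtype behavior matrices. An identical raw-value
   clustering arm provides the contrast.

Because real decedent EHR data cannot be redistributed, the package ships
a first-class synthetic cohort generator (`predeath.synthetic_cohort`)
that emulates the relevant structure — terminal drifts with staggered
onsets, latent trajectory subtypes with heavily overlapping single-analyte
margins, irregular ~5-day visit gaps, per-analyte missingness, skewed
benign-side dispersion — together with ground truth, so every claim the
framework makes is testable end to end. See `docs/methods.md` for the
generative model and its limitations.

## Worked example

Scripts under `examples/` exercise one capability each. Training horizon
models on a 300-patient synthetic cohort (`examples/train_horizon_models.py`):

```
 horizon  n_patients  mean_auroc  sd_auroc
       1         277       0.992     0.007
      30         273       0.976     0.013
      60         266       0.844     0.014
      90         265       0.671     0.040
Spearman(horizon, AUROC) = -1.00 — models closer to death discriminate better
```

Discrimination decays monotonically with distance from death, because the
planted terminal drifts have not yet begun far from death.

Stratifying 500 patients by day-1 attributions
(`examples/stratify_subtypes.py`):

```
silhouette selects k = 3; subtype sizes: {1: 192, 2: 122, 3: 163}
agreement with planted truth (ARI): 0.87
raw-value clustering ARI: 0.08 (the same structure is invisible in raw space)
```

The three planted trajectory subtypes are recovered almost perfectly from
attribution space (adjusted Rand index 0.87), while the identical
Ward/Euclidean procedure on standardized raw day-1 values finds almost
nothing (0.08) — raw Euclidean distance is diluted by wide
clinically-unremarkable dispersion that the mortality model, being
threshold-based, ignores. `examples/attribution_behaviors.py` shows the
matching importance trajectories, including a late-onset marker (drift
beginning 30 days before death) whose rank jumps from 75 to 1 as death
approaches.

The same analysis runs as one reproducible, config-driven pipeline:

```bash
predeath run-all --n-patients 300 --horizons 1,15,30,45,60,75,90 \
    --seed 0 --outdir run/
```

which writes every stage's CSV artifacts plus a `manifest.json` with the
config hash and artifact digests (identical configs reproduce identical
digests).

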