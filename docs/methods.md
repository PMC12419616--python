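# Methods

This note documents the statistical machinery, the synthetic cohort it is
validated on, and the judgment calls made where the design was genuinely
open. Nothing here reports a number that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The analysis

### Time axis and resampling

All analysis uses a days-before-death axis: death is day 0 and time
increases into the past. Calendar-stamped inputs are aligned once at
ingest against a per-patient death date (`preprocess.align_to_death`).

Raw events are deduplicated (first test per patient, day, and analyte —
by timestamp when present, else stable input order), analytes observed in
more than half of the patients are retained (strict inequality; a
parameter seen in exactly half is dropped), and each patient's series is
smoothed onto a dense daily grid with a moving average. The default
window is 5 days, matching the cohort's median inter-test gap, and is
*centered* (day *t* averages raw values in [t−2, t+2]); a trailing
alignment ([t, t+w−1], i.e. using only information at least *t* days
before death) is available by configuration. Centered alignment is the
default because it is symmetric around the queried time point; nothing in
the analysis depends on future-relative-to-query information since every
patient is already dead at analysis time. Grid cells whose window holds
no observation stay masked; no value is ever imputed — the boosted-tree
models route missing values natively.

### Horizon datasets and models

For horizon *n*, the positive example is a patient's day-*n* grid row and
the negative example the same patient's day-168 row; patients need at
least `min_observed` (default 1) unmasked analytes at *both* anchors.
"Availability at a time point" under partial missingness is not otherwise
well defined, so the threshold is an explicit knob. The construction makes
every dataset exactly 1:1 balanced, which is why no rebalancing machinery
exists.

Each horizon gets an independent LightGBM binary classifier. Defaults
(400 trees, learning rate 0.05, 31 leaves, `min_child_samples` 20,
feature subsampling 0.9, L2 = 1, single-threaded and deterministic) are
sized so that a ~500-patient cohort trains in about a second per horizon
while still resolving the individual contributions of many weak analytes.
Optional hyperparameter search is a seeded random search over learning
rate, leaf count, depth, minimum child samples and L1/L2, scored by AUROC
on the validation patients only; the final model refits on
train(+validation, configurable). Test patients are never touched by
selection.

All splitting is at the patient level (a patient's positive and negative
rows always share a fold), because the same patient appears on both sides
of the label; row-level splits would leak. Performance is the mean ± sd
AUROC over patient-level 5-fold CV.

### Attribution behaviors

Attributions are exact tree-path-dependent Shapley values in raw-margin
(log-odds) space, computed by the ensemble itself; every row satisfies
base + Σⱼ φⱼ = margin to 1e−6 (asserted at panel construction). The tests
check this algorithm against an independent brute-force Shapley
enumeration (cover-weighted conditional expectations over all feature
coalitions) on a depth-2 tree.

Behavior estimation keeps only *correct positives* — truly positive rows
with predicted death probability ≥ 0.5 (the threshold is configurable;
0.5 is the natural default for balanced classes). Per horizon, each
analyte's signed mean attribution m_j is scaled by max_k |m_k|, so the
dominant analyte's trajectory touches ±1 at every horizon. Signed means
(not mean |φ|) are used: on correct positives attributions are
predominantly risk-increasing, and sign carries the direction of the
effect. Rankings and importance shares use |·|; shares are percentages of
Σ|m_j| and always sum to 100. Horizons whose filtered panel is empty are
*absent* from the behavior matrix, never recorded as zero. The scale
divisor is the max over features of the |signed mean| (not a per-row
max), so the top feature's trajectory is pinned to ±1 — the reading under
which cross-horizon comparison of the remaining features is meaningful.

Panels are computed on held-out test rows by default; a full-cohort mode
exists and is used for desk-scale synthetic runs, where the test split
would leave too few rows for stable clustering.

### Embedding

Features with ≥ 10% masked patients at *any* used horizon are removed
(strict `< max_missing` at every horizon), then (patient, horizon) rows
with any remaining missing raw value are dropped — rows, not whole
patients, since a patient may be complete at some horizons only. The
attribution and raw variants share an identical row index; the raw
variant is standardized per feature before embedding. UMAP runs with
euclidean metric, 10 neighbors, `min_dist` 0.5 and a fixed seed; t-SNE
and PCA are available under the same interface. All horizons' rows are
stacked into one joint embedding — the only reading in which movement
over time is meaningful in a shared coordinate frame.

"Temporal structure is visible" is operationalized as the
temporal-separation score: the larger |Spearman correlation| between
horizon and either embedding coordinate. On the synthetic cohort the
attribution variant scores far above the raw variant under the UMAP
settings above (e.g. 0.33 vs 0.04 at the pinned seed). This contrast is
**method-sensitive**: under PCA the raw variant's leading variance axis
partially tracks time while the attribution embedding organizes by
subtype instead, and the ordering can reverse. The claim this package
tests is the UMAP operationalization.

### Stratification

Day-1 (one day before death) correct-positive attribution vectors are
clustered with Ward linkage under Euclidean distance. Each attribution
dimension is standardized first (constant dimensions — analytes the model
never used — drop out). This preprocessing is deliberate: boosted
ensembles spread credit unevenly across near-equivalent analytes, and
unstandardized Euclidean distance would inherit that arbitrary weighting;
standardization makes the procedure robust to it. It can be disabled
(`standardize=False`) to cluster raw φ.

k is the silhouette argmax over 2..10, with the within-cluster-variance
elbow curve emitted alongside for inspection; a fixed k can be forced to
reproduce a manual dendrogram cut. The raw-value comparison arm runs the
identical procedure on per-feature standardized day-1 raw values of the
same patients, after dropping rows with missing values. Note an inherent
asymmetry: attribution vectors are complete by construction (missing
inputs still receive a φ), while the raw arm loses the patients with any
missing day-1 cell; this mirrors the fact that raw-value analysis cannot
absorb missingness the way tree models do.

Subtypes are profiled by per-subtype median (IQR) for focus labs,
Kruskal–Wallis omnibus tests per lab and chi-square (Fisher's exact for
sparse 2×2) tests for categorical attributes, Holm-corrected *across the
omnibus family*; pairwise Mann–Whitney follow-ups run only where the
omnibus rejects and are Holm-corrected within each lab. This hierarchical
scheme controls the family-wise error at α (default 0.01); under a
simulated global null the corrected any-rejection rate is ≈ 0.01 over
1000 replicates (asserted ≤ 0.015 in the tests). Rank-based tests match
the median/IQR reporting convention for skewed lab values. Subtypes with
fewer than 3 patients are excluded from testing and flagged.

## 2. The synthetic cohort

### Generative model

Every patient dies at day 0 and is observed over the final 365 days (no
censoring — a decedent-only design). Patient *i* with latent subtype *z*
has, for analyte *j*:

    value_ij(t) = b_zj + d_zj · ramp(t; o_zj) + u_ij + ε_ijt

* `ramp(t; o)` is 0 for t ≥ o and rises linearly to 1 at t = 0 — the
  simplest shape matching the monotone terminal drifts of real decedent
  labs (albumin falling; CRP, LDH, BUN rising). The shape lives in one
  function (`latent_mean`) and is pluggable.
* `u_ij` is a patient random intercept with sd τ_j, built from a shared
  per-patient *frailty* factor (correlation ρ across analytes, oriented
  along each analyte's "worse" direction) plus an idiosyncratic part
  whose *benign-side* deviations are stretched by a factor c
  (`benign_spread`). Real analytes vary widely in their clinically
  unremarkable range for reasons unrelated to dying (CRP spans orders of
  magnitude in the well population); c > 1 reproduces that long benign
  tail. The stretch barely moves rank-based quantities (two-sample AUC
  overlap) but dilutes variance-based ones (standardized Euclidean
  distances) — the asymmetry that lets threshold-based tree models
  succeed where raw-value geometry fails, and therefore the mechanism
  behind the package's central clustering contrast.
* `ε_ijt` is i.i.d. Gaussian measurement noise with sd σ_j.

Visits are a renewal process with gaps in {g−1, g, g+1} days with
probabilities (0.25, 0.5, 0.25) around the configured median gap g
(default 5, so the pooled median is exactly 5), anchored near death —
hospital decedents have laboratory work at or just before death. Each
measured value is independently dropped with a per-analyte missing rate
(missingness is completely at random; no informative-missingness
mechanism is modeled).

### The three-subtype study scenario

`three_subtype_scenario` fixes the study conditions used throughout the
tests and the acceptance script: 77 analytes, mixing proportions
(0.45, 0.30, 0.25), ρ = 0.15, c = 4.

* Every *informative* analyte belongs to one signal class — between-
  patient sd 1.5 and noise sd 0.6 in unit scale, strong/weak drift
  2.73/0.63 — with clinical units entering only as per-analyte scale
  factors. Subtype identity is carried by *drift-magnitude modulation*:
  each of 66 generic analytes drifts strongly in one subtype and weakly
  in the others (22 per subtype), with alternating signs and onsets
  staggered over {90, 110, 130} days.
* Named labs follow the same class: albumin falls least in subtype 0
  ("maintained"), CRP rises least in subtype 1, LDH rises most in
  subtype 0, and BUN has onset 30 days with a mildly elevated drift —
  the archetype of a late-onset marker whose importance surges only near
  death.
* 5 pure-nuisance analytes never drift; 2 more carry 35% event
  missingness and exist to exercise the high-missingness filter (in the
  motivating real-data setting most analytes fail that filter too).

The strong/weak contrast of 2.1 units was calibrated so that the
*largest* pairwise day-1 separation AUC between subtypes, over all
analytes and subtype pairs at n = 3000, stays below 0.75: no single
analyte's day-1 marginal identifies the subtype, while the joint pattern
over ~44 differing analytes does. This is the precondition that makes
subtype recovery from attribution space a non-trivial claim. Two design
facts discovered while building the scenario are worth recording: (i)
subtype structure must live in analytes the model actually uses — drift
modulation of universally drifting analytes — because a well-fit model
attributes nothing to features that only matter for a subtype it can
already classify without them; and (ii) Ward/Euclidean clustering at this
capped per-analyte separation needs on the order of 20 informative
analytes per subtype, which is what fixes the panel at 77.

### What the generator does not emulate

Linear ramps only (no non-monotone or relapsing courses); missingness
completely at random (real testing intensifies when patients deteriorate);
Gaussian cores with a two-sided-scale skew rather than genuinely
log-normal assays (summary IQRs can extend below physical zero); no
censoring, no survivors, no comorbidity or treatment structure; a generic
categorical attribute in place of diagnosis coding. Passing tests on this
cohort therefore demonstrate that the pipeline recovers planted structure
of the stated kind under realistic sampling noise — not that any
particular clinical cohort contains such structure.

## 3. Numerical and reproducibility choices

* Problem sizes: tests and the acceptance script use 500 patients, a
  sparse horizon grid {1, 5, 15, 30, 45, 60, 75, 90}, and full-cohort
  attribution panels; these sizes give stable statistics (CV AUROC sd
  ≈ 0.01–0.04, ARI well away from decision boundaries) at desk scale.
* Determinism: LightGBM runs single-threaded with `deterministic=True`;
  every random draw in the pipeline descends from the single config seed;
  UMAP is seeded (which forces single-threaded layout). Identical configs
  reproduce identical artifact SHA-256 digests, asserted in the tests.
* Ties in importance ranking break lexicographically by analyte name.
* Degenerate inputs fail loudly: single-class training data, empty
  correct-positive panels, all-zero attribution scales, empty missingness-
  filtered feature sets and sub-minimum cluster sizes all raise with
  specific messages rather than propagating NaN.
* The 0.5 correct-positive threshold, the 168-day negative anchor, the
  5-day window and the 10% missingness cap are all configuration fields;
  their defaults are the study conditions described above.

## 4. Known limitations

* The embedding contrast is established for the stated UMAP
  hyperparameters; it is not claimed for arbitrary embedding methods (PCA
  can reverse it, see §1).
* The raw-value clustering arm operates on fewer patients than the
  attribution arm whenever day-1 missingness is non-trivial (rows with
  missing cells are dropped rather than imputed).
* Hyperparameter search is a random search with a modest default budget;
  it makes no claim of matching a dedicated tuner's optimum, only of
  honoring the train/validation/test contract.
* Synthetic CV AUROCs are somewhat higher than typical real-EHR values at
  matched horizons because the generator's noise is well-behaved; the
  monotone decay with horizon, not the absolute level, is the property of
  interest.
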