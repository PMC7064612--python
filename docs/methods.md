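# Methods

This note documents the models and numerical choices behind `monopheno`:
the gating pipeline, the quantitation and profile machinery, the synthetic
cohort that the test suite validates against, and the known limits of
both.

## Gating model

The pipeline reproduces a manual gating strategy as a deterministic
sequence. All fluorescence thresholds are closed below (`value >=
threshold` is positive), and every stage either labels an event or leaves
it explicitly `unassigned` — nothing is silently dropped.

**Positivity thresholds.** The lineage, CD14 and CD16 thresholds default
to the empirical quantile of the matched isotype-control channel that
excludes 99% of the isotype signal (`isotype_exclusion`, default 0.99).
The quantile uses linear interpolation, with a bump to the next order
statistic on heavily tied samples so that the "at most 1% strictly above"
contract always holds. A consequence of any percentile policy is a known
leakage floor: the same fraction of truly negative events lands above the
threshold. Because isotype reagents report Fc-mediated nonspecific
binding, their background is typically somewhat broader than the
unstained-channel background of the antibody tube, which places the
threshold above the bulk of the negative population and keeps that
leakage in the sub-percent range.

**Scatter split.** CD14⁺ events are modelled in (log FSC-A, log SSC-A),
standardized per axis, with a full-covariance Gaussian mixture. The
component count is chosen by BIC among {2, 3}: two components describe a
clean small/large pair; a third, when supported, absorbs off-cluster
events (debris, aggregates, smeared pulses) that a manual analyst would
leave outside every polygon. Components are identified by their FSC-A
means — lowest is the small-monocyte cluster, highest the large one; a
middle component is never a monocyte cluster. An event is assigned to its
maximum-posterior component only if the posterior reaches
`posterior_floor` (default 0.8) **and** it lies within the component's
Mahalanobis fence (`mahalanobis_limit`, default 3.5, i.e. ~99.8% coverage
of a bivariate normal cluster — the automated counterpart of a generous
manual polygon); otherwise it is `unassigned`. The mixture is fitted on
row-sorted data with a fixed random state, so results are deterministic
and invariant to event order. Degenerate single-mode scatter returns
all-small with a warning rather than an error.

**Doublet exclusion** operates per scatter cluster, never across
clusters. A doublet integrates roughly twice the pulse area of a singlet
at a singlet-like peak height, so it falls far below the FSC-H-on-FSC-A
ridge. The ridge is fitted with Theil–Sen regression on the unique
(FSC-A, FSC-H) support (evenly subsampled in sorted order above
`max_theilsen_points` = 2000 — deterministic and invariant to both event
order and exact duplication); events outside ±3 scaled MADs of the
residual ridge are excluded, and an FSC-W fence at the 99.5th percentile
(inverted-CDF quantile) of the residual-pass core removes wide pulses the
height test misses. Clusters below `min_cluster_events` (50) skip doublet
exclusion with a warning inside the full pipeline, and raise when the
stage is called directly.

**CD14/CD16 classification.** The CD14 dim/bright boundary defaults to
the valley of a Silverman-bandwidth KDE of log CD14 within the
small-cluster singlets, located between the two most prominent modes; a
configured quantile (0.15) is the unimodal fallback. The small cluster is
then split by the 2×2 rule (CD14 bright/dim × CD16 ±); the large cluster
into la14⁺16neg / la14⁺16⁺, with CD14-dim large events reported
`unassigned` (no large-dim class is defined). Optional per-channel upper
fences (`cd14_upper`, `cd16_upper`) bound the classification gates the way
manual rectangles do: events above a fence are `unassigned`. The plain
`GateConfig` leaves the fences infinite (a total rule); the packaged
default configuration sets them finite because the manual gates the
pipeline emulates do not tile the CD14/CD16 plane — their percentages sum
to ~87% of a cluster, not 100%.

**Denominators.** Cluster percentages are relative to CD14⁺ singlets
(assigned small + assigned large + unassigned events); subpopulation
percentages are relative to their own cluster's singlets, including
events the classification leaves unassigned. Children therefore sum to at
most 100% of their parent.

## Quantitation and nomenclature

Specific MFI is `statistic(antibody) − statistic(isotype)` with the
arithmetic mean as default statistic (median available as config; which
averaging a cytometer's software applies is instrument-dependent, so the
choice is explicit). Negative values are reported unchanged and binned
`neg`. Percent positive counts events at or above the positivity
threshold. Qualitative bins: percent positive < 10 → `neg`, < 35 → `lo`,
< 70 → `int`, else `hi`; specific MFI is binned per marker at 5% / 25% /
60% of that marker's cohort 99th-percentile specific MFI (`neg`/`dim`/
`med`/`bri`). The MFI cutoffs are relative to the cohort because absolute
fluorescence units are instrument- and voltage-specific; the fractions
are package defaults, fully configurable, chosen to preserve the ordering
dim < med < bri over the synthetic cohort's intensity scale.
Subpopulations with fewer than `min_events` (30) events are flagged low-n
and should not be over-interpreted.

## OP profiles and donor clustering

OP rules are data (`data/op_rules.json`), one conjunction of per-marker
bin clauses per profile id, covering the adhesion-molecule profiles of
all six subpopulations (OP-01…OP-05, OP-10…OP-12, OP-20…OP-22,
OP-30…OP-33, OP-40…OP-44, OP-50/51). Rules are evaluated most-specific
first (clause count, ties by id), which realizes the intended carve-out
structure — variant profiles (extra clauses) take precedence over their
base profile. OP-42/43/44 are shipped as placeholders (their ids are needed by the
donor-connectivity table but no complete definition exists); placeholder
rules without clauses are never matched.

Donor clustering builds the bipartite donor–profile graph, projects it
onto donors with shared-profile edge weights, and extracts communities by
greedy modularity maximisation (networkx), which is deterministic for a
fixed node insertion order (donors sorted). Multi-donor communities are
labelled I, II, … by their smallest donor id; singletons are
non-clustered. Modularity clustering was chosen over layout-based visual
grouping because it is reproducible and testable; on the packaged
donor–profile reference table it reproduces the published membership of
the first cluster exactly.

## Component subpopulations and profiles a–e

Within sm14⁺16⁺ cells, the three adhesion markers CD43/CD49d/CD62L are
reduced to neg/dim/hi levels per marker: `neg` below the positivity
threshold, `dim` vs `hi` split at the geometric midpoint of the two
configured stained modes (300 and 3000 units by default → split ≈ 949).
Component boxes on that grid: P1 = CD43hi·CD49dhi·CD62Lhi, P2 =
CD43neg/dim·CD49dhi·CD62Ldim, P3 = CD43neg·CD49ddim·CD62Lhi, an
intermediate box between P1 and P2 (CD43dim·CD49dhi·CD62Lhi), and the
donor-10 major box (CD43hi·CD49dhi·CD62Ldim; its minor companion falls in
the P1 box). A component is present when at least 5% (`min_fraction`,
configurable; there is no standard value for this floor) of the events fall in
its box. Present-set → profile letter is an exact-match table: {P1,P2,P3}
→ a, {P2,P3} → b, {P1,Pint,P2} → c, {P1,P2} → d, the donor-10 pattern →
e, anything else unclassified.

## Imaging features

Aspect ratio is minor/major axis of the CD14-delimited mask; the
singlet/doublet threshold is the minimum of a Silverman-KDE between the
two most prominent modes of the pooled aspect-ratio distribution, falling
back to 0.7 (a conventional bar position for round singlets) for small or
unimodal samples. Doublet percentage per gate is the share of objects
strictly below the threshold. Circle-equivalent diameter is
`2·√(area/π)`; because "diameter inferred from cell size" can mean either
the diameter of the mean area or the mean of per-object diameters, the
report emits both, labelled.

## Synthetic cohort

The generator emulates the study conditions the pipeline targets: 28
donors, 10⁵ events per donor (acquisition-scale runs used ten times
more; the default keeps a full cohort within desk-scale runtime and is
configurable upward), three staining sets sharing the lineage channel,
CD14 and CD16, with matched isotype tubes (2×10⁴ events).

* **Composition.** Events are lymphocytes (60%), CD14-negative others
  (10%) and CD14⁺ cells. CD14⁺ cells split into the small cluster (mean
  78.4%), the large cluster (mean 8.8%, floored at 2% — the large cluster
  is visible in every donor) and an off-cluster smear. Within-cluster
  compositions follow the published cohort means (77.2/4.4/3.2/2.4% small;
  79.2/10.0% large), with the CD14dim16neg subpopulation present in
  donors 1–16 only (16 of 28; which donors carry it is not recorded, so
  the choice is arbitrary and configurable). Remainder masses at every
  level are concrete truth classes that the gates leave unassigned: the
  scatter smear sits far off both clusters in SSC, the within-cluster
  smears are CD16-superbright events above the classification fence, and
  half of the large-cluster remainder is CD14-dim.
* **Per-donor variation.** At each composition level the minor fractions
  and the remainder are drawn with mean-preserving symmetric clips around
  their configured means, and the dominant fraction is their complement —
  so every configured cohort mean is exact by construction and no capping
  bias accumulates. Setting the SDs to zero fixes all fractions exactly.
* **Intensities.** All channels are log-normal. Stained-marker models are
  parameterized by intended (MFI bin, percent bin) pairs and back-compute
  the positive-component median from the target population-level specific
  MFI; each subpopulation carries one representative expression profile.
  sm14⁺16⁺ adhesion markers are drawn instead from per-donor component
  mixtures following the published donor groups. Isotype channels share a
  background model that is slightly broader (log-SD 0.5 vs 0.4) than the
  antibody-tube unstained background, as real isotype controls are.
* **Doublets** (2% of events) are synthesized from pairs of singlets:
  areas and fluorescence add, heights keep the larger pulse, widths widen
  by a factor 1.8 — which makes both the height-vs-area and the width
  discriminants work for the same physical reason they work on a
  cytometer.
* **Imaging objects** use mask areas whose means invert to the published
  singlet diameters (11.98 and 12.84 µm), 15% area CV, aspect-ratio
  models at 0.95 ± 0.03 (singlets) and 0.55 ± 0.08 (doublets), and 3%
  doublet contamination of each singlet gate.

Everything is a deterministic function of (config, seed) via per-donor
and per-tube substreams.

**What passing on this cohort does and does not show.** The generator
realizes the assumptions the pipeline relies on: log-normal intensities,
well-separated scatter clusters, background-identical isotype channels,
idealized pulse geometry, no spillover or compensation artifacts, no
acquisition drift, and marker independence within a subpopulation
(outside the modelled component structure). Recovery of the configured
frequencies therefore validates the pipeline's logic and calibration, not
its robustness to instrument effects absent from the model. On real data
the scatter clusters can overlap more, isotype backgrounds can mismatch
antibody conjugates, and the CD14 dim/bright valley can be shallow — the
config exposes every threshold so such cases can be gated with explicit
values.

## Numerical and design choices

* Quantile dialect: linear interpolation throughout (documented because
  dialects differ), with the discrete-sample correction described above
  for the isotype threshold; the FSC-W fence uses the inverted-CDF
  quantile for duplication invariance.
* GMM: full covariance, 10 initialisations, k-means++ seeding, fixed
  random state; BIC for component count.
* KDE: Silverman bandwidth for both the CD14 valley and the aspect-ratio
  nadir; peaks by prominence (1% of the density maximum); the valley is
  the argmin between the two most prominent peaks.
* Ties and order: all fits are performed on sorted/unique supports, so
  results are invariant to event order and to exact duplication.
* Reference-gene handling in 2^−ΔΔCt: the ΔCt reference may be a list of
  internal-control Cts, which are averaged; single-control mode is the
  one-element case.
* Binomial intervals: Wilson score at the 98% level (Wilson behaves well
  at the small cluster sizes involved).
* Below-LOD cytokine values are flagged, never imputed.

## Limitations

* FCS ingest is not implemented; CSV is the normative interchange format.
* The OP rule transcription is a faithful but necessarily interpretive
  encoding of prose descriptions; it ships as an editable JSON file
  rather than code for that reason.
* With three-component scatter fits on data that genuinely contains only
  two clusters, BIC almost always selects two components; if it selects
  three, part of a real cluster can be reported unassigned. Configure
  `scatter_components=(2,)` to force the two-cluster model.
* The component-box grid quantizes each adhesion marker to three levels;
  populations straddling a cutoff blur across boxes. The presence floor
  (5%) and the mode positions are configuration, not biology.
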