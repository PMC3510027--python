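# Methods

## Scope and data model

`screensift` models the computation of an arrayed RNAi suppressor screen
in five stages. The in-memory interchange objects are deliberately plain:
per-well activities and normalized values travel as pandas DataFrames,
the ontology as an is_a-only `networkx.DiGraph`, annotations as
`gene -> set(term)` dicts, and networks as `networkx.Graph`s with a
`relation` edge attribute. The two statistically substantive stages are
exposed as model/results pairs (`SuppressorScreen.fit() -> ScreenResults`,
`ParentChildEnrichment.fit() -> EnrichmentResults`); parsing, simulation
and network construction are function-level APIs.

## Activity quantification

Activity is the ordinary-least-squares slope of RFU over time divided by
per-well protein mass (RFU·min⁻¹·mg⁻¹). OLS is used because it is the
standard estimator for initial-rate kinetic assays and is exact on
noiseless linear data for any read spacing (both 44-minute and
sub-minute grids are exercised in tests). Negative slopes are reported
unmodified; clipping would bias downstream control ratios. The slope is
computed from centered sums, which is numerically stabler than the raw
normal equations; the tests compare against the raw normal-equations
form at 1e-9.

Degenerate inputs are hard errors: duplicate (plate, well, time)
triples, non-numeric fields (reported with the file line), fewer than
two reads, a constant time axis, and nonpositive protein mass.

## Normalization and hit calling

Two-stage normalization, in this order:

1. **Position**: each well value is divided by the mean of that grid
   position across all plates of the same screening day (a *batch*,
   typically 28–30 plates when ten library plates are screened in
   triplicate). Control wells are included in the per-position averages;
   they occupy fixed positions, so their averages are taken over like
   wells. The per-position mean of the output is exactly 1.
2. **Negative control**: each value is divided by the arithmetic mean of
   the plate's own negative-control wells (mutant construct +
   non-targeting siRNA), computed after position normalization, mapping
   that mean to 1.

A plate-mean normalization is deliberately not offered: arrayed
libraries are laid out by gene family, so plate means are confounded
with biology.

Replicates are aggregated as arithmetic mean and SEM (sample SD, n−1
denominator, over √n). Records need at least two surviving replicates;
failed wells are dropped pairwise. The screen-wide SD of per-pool means
uses the n−1 denominator by default (`ddof` is exposed; at thousands of
pools the choice is negligible). The hit rule is strict:
`mean + SEM < 1 − σ_screen`. A symmetric enhancer flag
(`mean − SEM > 1 + σ_screen`) is attached for convenience but not
analyzed. When one gene is covered by several pools, `gene_rollup()`
keeps the pool with the minimum mean + SEM per gene.

The packaged 130-row suppressor reference table carries published
normalized means and SEMs; re-scoring it with the published screen SD of
0.317 flags all 130 rows at the cutoff 0.683 and reproduces the printed
ranking (ascending mean).

## Parent-Child-Union enrichment

Annotations are first closed under the true-path rule (a gene annotated
to a term is annotated to every is_a ancestor). Only is_a edges define
the DAG; other OBO relations are ignored. For a term *t* with parents
pa(*t*), the test statistic is the hypergeometric upper tail of the
study count of *t* within the parent-union universe — population genes
annotated to at least one parent — with the study-side draw size being
the study genes in that universe. A root term degenerates to the classic
term-for-term test. Conventions for degenerate cases: no study gene in
the parent union → p = 1 (logged); a term annotated to its whole parent
union → p = 1 automatically (the tail saturates).

The BH family is exactly the tested terms (every term with ≥ 1
propagated study gene), following the convention of DAG-aware
enrichment tools. Step-up adjustment is implemented directly (and
checked in tests against both a sort-and-cummin reference and
statsmodels).

Three filters produce the final `kept` set:

* `p_adjusted ≤ alpha` (default 0.05);
* `level > min_level` (default 2), where level is the shortest is_a
  distance from the namespace root (root = 0) — near-root categories
  are uninformative; levels are computed per-namespace root;
* when a screened-library gene list is supplied, a pooled two-proportion
  z-test compares the category's frequency in the study set against the
  library and drops categories with two-tailed p > 0.05. The raw
  (unadjusted) two-proportion p is used for this QC threshold. The
  population (background) set is an explicit input and should normally
  be genome-wide — a screened library is usually too small to power the
  main test, which is exactly why the QC comparison is a separate,
  simpler statistic. Categories under-represented in the study set are
  flagged `depleted` so callers can drop them; by default they are
  retained because the filter is two-tailed.

Degenerate QC inputs (pooled proportion 0 or 1) return p = 1 with a
`degenerate` flag rather than an error. All tested terms are returned
with their filter outcomes so exclusions are inspectable; the DOT export
draws kept terms plus their ancestors, colored by namespace with
intensity scaled by −log10 p_adjusted.

## Hit networks

The direct network is the induced subgraph on seed (hit) genes with
isolated seeds removed; it is idempotent. A focus gene can be added
manually with all its interactome edges to current members (kept even
if isolated, flagged `focus`). The shortest-path network examines, for
every seed pair, the interactome's shortest paths; a pair is connected
when some shortest path has at most `max_intervening` (default 1)
non-seed interior nodes, and among qualifying shortest paths the one
with the lexicographically smallest interior node sequence (source <
target) is kept — an explicit, deterministic surrogate for proprietary
"shortest path" network builders whose connector-reuse strategy is
unknowable. With `max_intervening = 0` the construction reduces to the
direct network plus isolated seeds, and member sets grow monotonically
in `max_intervening`. Both direct and indirect relations are traversed
by default; `direct_only` restricts to physical-contact edges.
Shortest-path enumeration is exhaustive per pair, which is exact but
assumes interactomes of moderate density.

## Synthetic-data generators

All generators are pure functions of their parameters and seed
(byte-identical outputs are asserted in tests) and emit the exact text
dialects the pipeline consumes.

**Screen.** 96-well plates with 12 fixed control wells (3 × 4 roles in
columns 11–12) and 84 test wells; up to 10 library plates per day batch,
each screened in `replicates` (default 3) copies — a full day is 30
plates, mirroring common screen geometry. Per-well activity is

    base × plate_scale × position_factor × (effect + ε),

with log-normal position factors (σ = 0.15, drawn per day batch and
well), log-normal plate scales (σ = 0.05), and Gaussian replicate noise
ε (σ = 0.05 by default) on the effect scale — so a null pool's
normalized value is ≈ 1 ± 0.05 per replicate. Spiked suppressors draw
their effect from `effect_range` (default a point mass at 0.4);
control-role effects are fixed (negative 1.0, CASP3-positive 0.4,
wild-type toxicity controls 0.12/0.10). Kinetic reads are linear,
RFU(t) = 100 + activity·protein·t + N(0, 2 RFU), at five 44-minute
reads; protein is log-normal around 0.01 mg. With these defaults the
kinetic-fit and protein contributions to a normalized value are below
1e-3 relative — replicate noise dominates, which is what the
normalization stage is designed to confront. Test wells beyond the
library size are emitted as mock wells (null effect, no siRNA id) so
every plate shares the full grid geometry.

What the generator does **not** emulate: heavy-tailed or well-correlated
noise, edge-specific evaporation gradients (position factors are i.i.d.
across wells), transfection-efficiency drift across days, siRNA
off-target structure, or any real effect-size distribution. Passing
spike-in tests therefore demonstrates correctness of the computation
under the stated noise model, not performance on a real screen.

**Ontology.** A single-namespace layered DAG (default 200 terms, depth
5); each term draws 1–2 parents from the layer above, so layer index =
level. Genes (default 500) are annotated to random terms of layers ≥ 2
at rate 0.05. Planted terms sit in layers ≥ 3 — below the near-root
exclusion zone — and are over-annotated in a designated study set
(default 100 genes) at `fold` × the background rate (default 10×).

**Interactome.** A G(n, m) random graph (default 200 nodes, 500 edges,
30% indirect relations) decorated with a fully connected direct-relation
seed clique and seed pairs joined only through a planted connector;
background seed–seed edges outside the clique are removed and competing
one-hop bridges deleted, so the planted structures are exactly
recoverable and recovery can be asserted without slack.

## Calibration checks and problem sizes

The acceptance suite compares realized behavior against independent
oracles: exhaustive hypergeometric enumeration for the Parent-Child-
Union statistic (200 random DAGs of ≤ 12 terms / ≤ 15 genes),
sort-and-cummin BH on 1,000 random vectors at 1e-12, brute-force
induced-subgraph and all-pairs-BFS network oracles on 100 random graphs,
and a summary-level Monte-Carlo reimplementation of the screen noise
model (30 replicate simulations) for null hit-fraction and spike-in
recall, compared within three binomial SDs. Null and spike-in screens
use 2,000 siRNA pools in triplicate; null-enrichment calibration uses 20
seeded 120-term ontologies. These sizes give each check a few seconds'
runtime while keeping binomial slack tight enough to be informative.

## Known limitations

* The Monte-Carlo screen oracle shares the generator's independence
  assumptions; both would be blind to a mis-modeled correlation that
  affects pipeline and oracle identically.
* Shortest-path canonicalization is one defensible choice among several
  (global connector-reuse optimization is NP-hard in general and not
  attempted).
* The two-proportion QC filter uses the normal approximation; for very
  small categories an exact test would be preferable, but the filter is
  only a guard, not the headline statistic.
* Non-eukaryotic or otherwise unwanted categories are not auto-detected;
  curation remains the caller's responsibility (drop by term id from the
  returned results).
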