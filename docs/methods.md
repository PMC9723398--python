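# Methods

## Scope and model

phosphonet implements the threshold-based quantitative workflow used
downstream of SILAC phosphoproteomic quantification. It deliberately
contains no identification or localization machinery: the input is assumed
to be a site-level table of normalized heavy/light ratios per biological
replicate, as produced by a search engine's site export. Identification
FDR, phosphosite localization probabilities and protein inference are
consumed, not computed.

## Differential calling

* **Normalization.** Each condition-replicate ratio column is divided by
  2^median(log2 r) over its present values, so the column's median log2
  ratio is exactly zero (tolerance 1e-12 in tests). The upstream convention
  this mirrors is peptide-level median-zero normalization inside the
  quantification software; since our input is site-level, per-column median
  centering over all sites is the closest faithful analogue. The operation
  is idempotent and invariant to per-column multiplicative bias.
* **Comparisons.** A `ComparisonDesign` names its numerator and denominator
  condition explicitly, and the per-replicate comparison ratio is their
  quotient. This makes the heavy/light channel pairing of each comparison
  (constitutive at T0, agonist-induced at T3/T30, etc.) an explicit input
  rather than an assumption baked into column names; a condition measured
  against a common reference can therefore be re-referenced to any other.
* **Presence filter.** A site is positively quantified for a comparison iff
  at least `min_present` (default 2) of `n_replicates` (default 3)
  replicate pairs are present in both conditions. Sites failing the filter
  are routed to a `not_quantified` report, never silently dropped, so per
  comparison the labels partition the input: up + down + unchanged +
  not_quantified = n_sites.
* **Calls.** The geometric mean of the present replicate ratios is
  thresholded with strict inequalities: GM > 1.5 → up, GM < 0.67 → down
  (both correspond to >50% change), boundary values are unchanged. The
  geometric mean uses only the present replicates; no imputation. No
  multiple-testing correction applies — the calls are pure fold-change
  thresholds by design.
* **Protein level.** A protein is differentially phosphorylated iff ≥ 1 of
  its sites is regulated. When sites conflict, both directions are reported
  (`up|down`); no net call is invented, since any aggregation rule here
  would be arbitrary.
* **Set summaries.** For a receptor pair, per comparison: identifiers
  regulated only in A, only in B, shared with intersecting direction sets
  ("coherent") and shared with disjoint direction sets ("discordant") —
  both shared variants are reported because "shared" alone is ambiguous —
  plus per-receptor up/down kinetics counts.

## Kinase motif attribution

Matching is boolean and count-based (no position weight matrices): a 13-mer
window matches a motif iff its center is in the motif's acceptor set and
every constrained offset's residue is in the allowed set. Windows truncated
at protein termini are padded with `_`, which never satisfies a constrained
position. A site counts once toward every kinase it matches; the
per-receptor total is the number of (site, kinase) attributions, which is
the denominator of the percentage-ratio statistic. Ratios with a zero
denominator kinase are reported as +inf (attributed only in A) or NaN
(attributed in neither), never dropped.

The shipped default library (`PKA R-R-x-S*`, `AKT1 R-x-R-x-x-S*`,
`CK2 S*-x-x-E`, `CDK1 S*-P-x-[KR]`, `MAPK1 P-x-S*-P`, `GSK3B S*-x-x-x-S`,
`SRC [DE]-x-x-Y*`) is illustrative — a compact set of textbook consensus
motifs chosen to be pairwise non-subsuming, so a window can always be
constructed that matches exactly one of them. Results on real data depend
entirely on the motif library supplied; the default is not a curated
kinase-substrate resource.

## Network topology

* **Evidence filtering** keeps an edge iff experiments ≥ 0.15 OR databases
  ≥ 0.35 (inclusive); the two STRING-style channels are disjunctive.
* **Network build** is the induced subgraph on the DPP list; isolated DPPs
  remain as nodes. An opt-out is deliberate: retaining non-DPP first-shell
  interactors would change network sizes in ways that depend on the
  interactome release, so the default is the self-contained induced graph.
* **Centralities** follow the CentiScaPe definitions: betweenness
  Σ σ_st(v)/σ_st and stress Σ σ_st(v) over ordered pairs, unnormalized;
  closeness = 1/Σ d(v,t) and eccentricity = 1/max d(v,t) over reachable t;
  radiality = Σ (Δ+1−d(v,t))/(n−1) with Δ and n the component diameter and
  size; centroid(v) = min_w [γ_v(w) − γ_w(v)] with γ_v(w) = #{t : d(v,t) <
  d(w,t)}; eigenvector = principal adjacency eigenvector on the undirected
  view, scaled to unit maximum; bridging = betweenness × bridging
  coefficient (1/deg v)/Σ_{u∈N(v)} (1/deg u). Ordered-pair counting makes
  the undirected and directed conventions coincide and is fixed purely for
  reproducibility — hub selection is invariant to uniform scaling.
  Disconnected graphs: path sums run over reachable nodes only; isolated
  nodes score 0; no division by zero can occur. In signaling mode
  activation/inhibition edges are traversed only along their direction and
  docking both ways; edge signs carry semantics, not topology.
* **Hubs** are nodes with betweenness strictly greater than the arithmetic
  mean betweenness of the network they sit in. The rule is applied per
  network; averaging a node's betweenness across several time-point
  networks before thresholding is a plausible alternative reading and can
  be composed from the per-network profiles if wanted.
* **Null models.** Degree-preserving double-edge-swap rewiring: `n_swaps`
  (default 10 × edge count) attempted swaps, invalid moves (self-loops,
  duplicate edges) rejected without retry, so the degree multiset — in- and
  out-degree sequences in directed mode — is conserved exactly. Empirical
  p-values use the add-one estimator (1 + #{null ≥ obs})/(n_random + 1), so
  p ∈ (0, 1]; `n_random` defaults to 1000 for analyses and the pipeline
  default is 100. The per-replicate mean betweenness is emitted as a long
  table (replicate, statistic, value) ready for violin plots.

## Synthetic data generator

The generator emulates a two-receptor SILAC experiment: per condition and
replicate, a site's ratio is its true fold change (2.0 up, 0.5 down, 1.0
unchanged by default) times lognormal noise — normal on the log2 scale with
σ = `noise_sigma` — with replicates dropping out independently (MCAR) at
`missing_rate`. The reference condition centers on ratio 1, so the
stim-vs-ctrl comparison ratio carries the planted effect with noise from
both channels. Windows are random 13-mers centered on S/T/Y; a configurable
fraction of regulated sites gets a window rejection-sampled to match its
planted kinase's motif and no other library motif. Site universes
(identities, proteins, background windows) can be shared between receptors
via `universe_seed` while effects stay independent. Networks plant each
connector as the sole bridge between two otherwise unlinked communities, so
its betweenness exceeds the graph mean by construction; edge experiments
scores are drawn in [0.15, 1] so default evidence filtering preserves the
planted topology.

Defaults are chosen as plausible for replicated SILAC data — σ = 0.2 on the
log2 scale and 10% dropout — but `noise_sigma` is a free parameter, not an
estimate from any dataset: published site tables rarely report per-site
ratio variance. The generator does not emulate intensity-dependent
missingness, peptide-level correlation between sites of one protein,
ratio compression, or isotope-incorporation artifacts; passing tests
therefore demonstrate correctness of the analysis logic under a clean error
model, not robustness to every pathology of real MS data.

## Pipeline

One YAML config drives the run; unknown keys are rejected with their key
path, thresholds default to the values above, and exactly one of
`path`/`synthetic` is required per data source. Per-stage seeds derive from
the global seed as the first four bytes of BLAKE2s("<seed>:<stage>"), so any
stage is reproducible in isolation and reruns are byte-identical (floats are
written with `%.17g` and parsed with round-trip precision). The manifest
records a hash of the scientific config content (excluding output location),
the seed, per-stage counts and, for synthetic inputs, a truth-vs-called
confusion matrix. Stage failures abort with the stage name; no partial
artifact is reported as complete.

## Verification problem sizes

The test suite and `scripts/acceptance.py` use: 2,000 sites × 10 seeds for
parameter recovery (sensitivity ≥ 0.90, FDP ≤ 0.10 under σ = 0.2); 400-site
tables per receptor for exact motif recovery; all 143 connected graphs on
≤ 6 nodes plus 100 random ≤ 12-node graphs for the brute-force centrality
oracle; a 200-node scale-free network × 100 rewirings for degree
conservation; and 50 seeds of a 21-node two-community network (50 null
replicates) for connector significance and hub recovery. These sizes give
stable statistics while keeping a full run in well under a minute; all are
parameters, not limits.

## Known limitations

* Fold-change-only calling has no variance model; a site with erratic
  replicates but a large geometric mean is still called. This is faithful
  to the implemented workflow, not a recommendation against moderated
  statistics.
* Motif attribution is consensus-based and cannot separate kinases with
  overlapping consensus beyond what the library encodes.
* The eigenvector centrality of a disconnected graph concentrates on the
  component with the largest spectral radius; other components score ≈ 0.
* Double-edge-swap mixing is attempt-counted, not convergence-diagnosed;
  for very sparse graphs increase `n_swaps`.
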