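# Methods

## Model and procedure

### Delimitation space

A putative species is a contiguous, non-empty run of a host fig's ordered
elevation sites, encoded as an occupancy bit vector; contiguity is
evaluated on the host's own site list, so a host absent from some global
elevation still has gap-free ranges by index.  Within a host, a
delimitation hypothesis is an ordered partition of the site line into
contiguous blocks (sympatric species of one host never overlap in
elevation, matching the empirical networks the rules were derived from);
a host with *n* sites has n(n+1)/2 putative species and 2^(n−1)
delimitations.  A putative species combination (PSC) chooses one
delimitation per host; PSC ids are mixed-radix indices over hosts in
design order (last host fastest), fixed so ids are reproducible across
runs.  PSCs are generated lazily; the sweep never materialises the full
set of species objects.

### Strain ascription and purging

Communities — not hosts — are the unit of contact: a recent species
complex of several hosts is one community, since host-choice "mistakes"
can still move symbionts among its members.  If a community holds ≥ 2
putative species across its hosts, each receives a fresh strain label
(`w1`, `w2`, …, numbered globally in community/host/start-site order so
two communities never share a label); a single-species community is
entirely uninfected.

Distances between putative species are min-linkage: the minimum patristic
(path-length) distance over all cross pairs of member tips, in
substitutions per site.  At purge threshold *t*, a putative species
becomes uninfected iff its distance to **every** other putative species
of its community strictly exceeds *t* — i.e. purging is conservative: one
sufficiently close neighbour preserves the infection.  Equality keeps the
strain (the worked example purges at 0.06 > 0.05 and keeps at
0.03 < 0.05; ties are unspecified there, and strict exceedance is the
documented choice).  Purging acts on whole species: all members keep the
strain or all lose it; surviving labels are never renamed.

The threshold grid starts with an explicit *disabled* sentinel rather
than a numeric zero — "zero" in a sweep means *no purging*, whereas a
literal 0 under strict exceedance would purge everything — followed by
`n_steps` (default 100) evenly spaced values from the smallest positive
tip-to-tip distance to the whole-tree maximum.  The lower endpoint is a
choice (the smallest distance at which purging can first refuse to act);
it is reported in output metadata.

### Accuracy scores

All three scores share one statistic: in the contingency matrix of
ascribed rows × empirical columns, select at most one cell per row and
per column maximising the summed counts.  This is solved exactly as a
rectangular assignment problem (`scipy.optimize.linear_sum_assignment`);
because counts are non-negative, the optimum over partial matchings is
attained at a maximum matching, so the assignment solution is the score.
A greedy strike-out variant (rows in descending row-max order, clashes
falling through to the next unused column) is kept as
`greedy_match_score` for comparison; it agrees on the worked examples but
is not guaranteed optimal, which is why the exact solver is the default.

* **WIA** uses rows = ascribed positive strains, columns = empirical
  positive strains.  The none-token is never a matchable column:
  individuals ascribed a strain but empirically uninfected (or vice
  versa) contribute to neither axis, and the denominator is the
  empirically infected count.  Matching scope is global by default (each
  empirical strain column creditable once across the whole study); a
  per-community scope is available via `wia_score(..., per_community=…)`
  since an empirical strain shared by two communities is then creditable
  in each.  Global scope is the stricter reading and the default.
* **uWIA** is a direct count: individuals predicted uninfected whose
  typing is the none-token, over the empirically uninfected count.
* **PSC accuracy** applies the same matching to putative species ×
  empirical species over all individuals.

Tie-breaking among equally optimal matchings cannot affect the reported
score (only the total is used).

### Sweep and statistics

`run_sweep` evaluates every PSC × threshold.  Internally the work is
factorised by community: per-community candidate species, their
min-linkage distance matrix, purge survivals and contingency rows are
precomputed once per community-level combination, and only the global WIA
matching is solved per (PSC, threshold).  This is an implementation
detail — spot-check tests verify row-for-row agreement with the one-PSC
scoring path — but it is what makes the full 8192 × 11 sweep run in
seconds on one CPU.  Per row the table reports WIA, uWIA, PSC accuracy,
uWIA improvement over the disabled threshold at the same PSC, the same
improvement zeroed where WIA fell, and species richness.

Evaluation follows the study's analysis style: OLS (statsmodels) of PSC
accuracy against WIA with a cube transform of the response (a
variance-stabilising choice for bounded counts, selected from residual
diagnostics), a label-shuffling null (uniform seeded permutation of
empirical strain labels; a `clade` mode permutes (species, strain) pairs
jointly instead — the choice of what "shuffled associations" permute is
genuinely open, so both are exposed), and Welch's unequal-variance
*t*-test with Welch–Satterthwaite df.  p-values are reported, never used
for gating.

### Fecundity trade-off model

Parameters: brood size N, conspecific count N_c (π_c = N_c/N), per-egg
survivals ω_c, ω_h ∈ [0, 1] for conspecific/heterospecific offspring, and
ordered oviposition layers (capacity, survival coefficient) from the fig
centre outward with non-increasing coefficients.  Without CI all N eggs
fill layers centre-outward with the two egg types mixed in proportion in
every layer; with CI only the N_c conspecific eggs are laid, filling the
best layers first.  Egg counts are continuous (expected values) — the
closed forms are already fractional — and the same arithmetic reproduces
integer toy layouts exactly.

Defaults for the heat-map sweep: five layers with coefficients
(1, 0.75, 0.5, 0.25, 0); N = 100 with equal capacity N/5 = 20 per layer
(the zero-coefficient layer absorbs the overflow).  Equal per-layer
capacity makes the non-zero layers saturate at N_c = 80, which produces
the observed ceiling of the favoured fraction near 50% for high
conspecific-mating levels; with larger per-layer capacities the ceiling
drops well below that, inconsistent with the reported summary table.
The (ω_c, ω_h) grid is 100 × 100, cell-centred on (0, 1) — inferred from
the reported percentages being integer multiples of 0.01% — and the π_c
sweep is 0.05 … 0.95 in steps of 0.05.  All of these are configurable.
"CI favoured" means ΔW > 0 strictly; deltas within 1e-9 (relative) of
zero count as ties, so analytically exact ties (the ω_c = ω_h diagonal
once conspecific eggs saturate the non-zero layers) are not split by
floating-point round-off.

## Synthetic data generator

`generate_study` emulates the features the pipeline exercises: a rooted
tree whose clades mirror communities and species (root → community stem →
species stem → tips), a planted delimitation of contiguous elevation
blocks, distinct strains per species in multi-species communities applied
with penetrance 0.8 (dominant strains below fixation), uninfected
single-species communities, and 2% horizontal-transfer noise tips
carrying a random foreign strain.  Default sizes mirror the study scale:
253 individuals over six hosts (64/32/22/35/48/52), nine true species.
Branch lengths are uniform draws scaled so within-species distances
(≤ 0.008) sit far below between-species distances (≥ 0.25) and the tree
maximum is of order 0.5 substitutions per site, so purge thresholds sweep
a realistic range and min-linkage clustering is well-posed.

What it does **not** emulate: sequence-level evolution (no alignments or
MLST alleles), within-species infection polymorphism, paraphyly of strain
placement beyond what noise tips induce, unequal sampling across sites
within a host, and uncertainty in the tree itself.  Passing
parameter-recovery tests therefore shows the rules and scoring behave as
designed under clean clade structure — not that real data, with
introgression and estimation error, will score as high.

## Numerical and design choices

* Trees: newick input must carry branch lengths on every edge; plain
  newick with a bifurcating root is treated as rooted, a root polytomy as
  unrooted and midpoint-rooted with a warning (patristic distances are
  rooting-invariant, so scores are unaffected).
* Metadata: fixed CSV header `tip_id,host_fig,community,elevation,species,strain`;
  elevation labels are opaque ordered tokens; the none-token (default
  `none`, configurable at load) is reserved.  Individuals with missing
  strain typing must be given the none-token explicitly or excluded
  before loading — an empty strain field is normalised to the none-token
  at read time.
* Degenerate inputs: a tree with all-zero distances yields a
  threshold grid of the disabled sentinel only, with a warning; empty
  metadata loads as an empty list with a warning; empty contingency
  matrices score 0.
* Problem sizes in the shipped tests: the full 8192-PSC sweep at 11
  thresholds, the matching-solver cross-check on 520 random matrices up
  to 5 × 5, and 1000 random two-patch scenarios for the CI-dominance
  property — all chosen to exercise the complete study design while
  keeping the suite fast.

## Known limitations

* The purge rule is binary per species; partial penetrance of purging
  (some individuals losing infection) is outside the model.
* Unidirectional CI and within-species strain polymorphism are not
  modelled.
* The favoured-fraction table depends on the layer-capacity convention;
  only its qualitative trend (monotone rise from ~2% to ~50% over
  π_c ∈ [0.05, 0.90]) is asserted, not exact row values.
* Global vs. per-community WIA matching can differ when empirical strains
  recur across communities; the default (global) is the conservative
  choice and the alternative is one keyword away.
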