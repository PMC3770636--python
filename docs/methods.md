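# Methods

## The question and the two measurements

The package relates two per-character quantities measured on the same
discrete taxon × character data: how much a character *evolves* on a
phylogeny, and how *useful* it is in an interactive identification key.
Both are deliberately simple, assumption-light statistics.

### Parsimony steps (evolution)

Characters are unordered: any state can change into any other at unit
cost, with no ordering or step-matrix structure (identification-key
characters are unordered multistate by construction). The step count for a
character is the minimum number of changes over all assignments of single
states to internal nodes, computed with Hartigan's generalization of the
Fitch down-pass so that polytomies are handled exactly rather than being
arbitrarily resolved: at an internal node with `c` children, each state is
scored by how many child state-sets contain it; if the best score is `K`,
the node contributes `c − K` changes and passes up the set of states
attaining `K`. For binary nodes this reduces to the familiar
intersection/union rule.

Two semantics matter at the leaves:

- **MISSING** (unscored) leaves carry the full wildcard state set. They can
  never force a change, and replacing any scored cell by MISSING never
  increases the count (tested as a property).
- **Polymorphic** leaves carry their observed set; the count is therefore
  minimized over resolutions of the polymorphism.

Homoplasy is summarized with the classic indices. With `k_obs` distinct
observed states, `m = k_obs − 1` is the fewest changes any tree could
need; `g` is the count on a completely unresolved bush (scored leaves
minus the largest single-state-compatible group, polymorphic leaves
counting toward a state whenever their set contains it); `CI = m/s`,
`RI = (g − s)/(g − m)`. A character is called homoplastic when `s > m`,
i.e. CI < 1: the reconstruction must re-derive or revert some state. CI
and RI are reported as *undefined* (None/NaN) for degenerate characters
(invariant: `s = 0`; or `g = m`) rather than coerced to 0 or 1, so class
averages are never silently biased. Note that with polymorphic leaves the
`k_obs`-based minimum can exceed the bush bound (`m > g`), in which case
the `m ≤ s ≤ g` ordering is not guaranteed; the bounds invariant is only
asserted when `g ≥ m`.

Unordered parsimony depends only on topology, not on the root or the
branch lengths, and the implementation is tested for exact agreement with
brute-force enumeration of internal-node assignments on thousands of
random small trees, and for invariance under rerooting.

### Best score (utility)

An interactive key eliminates every active taxon whose cell for the
selected character neither contains the selected state nor is MISSING
(unscored taxa are never eliminated — eliminating a taxon because it was
not scored would be a false rejection). The ranking principle is that the
best character splits the remaining taxa most evenly. The exact scoring
used by commercial key software is unpublished, so the package defines its
own parameter-free realization of that principle, the **expected retained
fraction**: with `N` active taxa, `n_s` compatible with state `s`
(polymorphic taxa count for each of their states), `u` unscored, and
selection probability `p_s = n_s / Σ_t n_t`,

    b = Σ_s p_s · (n_s + u) / N .

`b = 1` exactly when no selection can eliminate anything; for complete
binary data `b` is the Simpson concentration `Σ p_s²`, minimized at the
most even split (verified exhaustively for all binary splits up to
N = 12). The steps-vs-rank correlation is robust to the choice among
monotone evenness measures, since Spearman's ρ only consumes the induced
ordering. Ties in `b` break by ascending character id, everywhere, for
determinism.

For the study analysis, ranking is computed **once on the full matrix**
(all taxa active), matching how a key's global character ordering is
assessed; the greedy identification engine (repeatedly take the
best-ranked usable character scored in the specimen, select the specimen's
state) is provided to measure key *depth* — how many selections isolate a
taxon — and is guaranteed to isolate exactly the taxa whose rows are
unique when the matrix is complete.

### The correlation

Steps and Best rank are paired per character; characters unusable for
ranking (fewer than two observed states) or never scored on the tree are
excluded and counted. Spearman's ρ is the Pearson correlation of
mid-ranks (scipy's implementation, cross-checked against an independent
longhand oracle to 1e-12). Significance is by permutation: exact
enumeration of all n! pairings for n ≤ 9, otherwise a seeded Monte-Carlo
test with the add-one estimator `(b + 1)/(n_perm + 1)` (default
`n_perm = 100,000`). The t-approximation is deliberately not used: the
character tables here are small and heavily tied. The same correlation is
computed within each declared state-count stratum; strata with fewer than
`stratum_min` (default 5) usable characters are reported "not tested"
rather than dropped.

Sign convention: rank 1 = most useful, so "faster characters are more
useful" manifests as negative ρ. The report states this convention.

## The simulator

The generator emulates the structure of a species-level key study; its
defaults are the study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `n_taxa` | 350 | taxa in the matrix (a large regional fauna) |
| `state_counts` | 19×2, 17×3, 8×4, 3×6 | 47 characters, 2–6 states |
| `rate_low`, `rate_high` | 0.05, 5 | log-uniform per-character rate, in expected changes per unit tree height (two orders of magnitude) |
| `missing_fraction` | 0.02 | unscored cells, completely at random (matrix > 95% complete) |
| `birth_rate` | 1.0 | Yule rate (only shapes relative node depths after rescaling) |

- **Trees** are pure-birth (Yule) with the stated tip count, rescaled to
  root height 1, so rates are interpretable as expected changes per tree
  height. No extinction, no fossil calibration — the empirical analog is a
  relative-time chronogram with no absolute ages either.
- **Characters** evolve under the Mk model (uniform root state, equal
  exchange rates), simulated as an explicit Poisson jump process per
  branch: the number of events on a branch of length `t` is Poisson(rate·t)
  and each event jumps uniformly to one of the other `k − 1` states. The
  realized event count is recorded because the whole point of the
  homoplasy analysis is the gap between true changes and the parsimony
  minimum (hidden and cancelling changes). Calibration (mean events ≈
  rate × total branch length) and saturation (steps plateau below the leaf
  count while true changes grow) are tested.
- **Missing data** is placed completely at random. Real missingness is
  structural — e.g. sex-limited organs or broken specimens — and therefore
  correlated across characters and taxa; nothing here models that, so
  passing tests say nothing about structured missingness.
- **DNA columns** are 4-state Mk sites in named rate classes
  (Jukes–Cantor-like), sufficient for per-class average-step comparisons
  against morphology; no transition/transversion bias, no among-site Γ
  variation within a class.
- **Matched-seed ladders**: per-character rate *quantiles* and the missing
  mask are drawn from dedicated seed-sequence child streams, so
  configurations differing only in the rate bounds share the same
  quantiles and the same missing cells. This makes rate-ladder
  monotonicity checks (homoplastic fraction and mean steps non-decreasing
  in the rate ceiling) sharp.

Determinism: every generator takes an explicit seed; two runs of the
pipeline with the same configuration produce byte-identical reports
(tested). Seeds passed on the command line are reduced mod 2³¹.

## A mechanism note on the flat-rate "null"

One might expect that simulating all characters at a single shared rate
destroys the steps-vs-rank correlation. It does not, and the package's
tests assert the correct behavior rather than a near-zero ρ: at a fixed
rate, the *realized* number of changes still varies across characters, and
a character that happened to change more is simultaneously steppier and
more evenly distributed at the leaves. The flat-rate correlation is
therefore genuinely negative but substantially weaker than under rates
spanning two orders of magnitude; rate heterogeneity contributes the
dominant share of the signal, and that contrast is what the test pins
down.

## Numerical and design choices

- **Newick round-trip** writes branch lengths with 12 significant digits;
  parsing is dendropy's, wrapped with this package's validation (unique
  non-empty leaf labels, non-negative lengths; zero-length branches are
  legal). Polytomies are preserved end to end.
- **Rerooting** reverses the parent chain edge-by-edge and does not
  suppress the degree-2 node it may create; total branch length and
  unordered parsimony are invariant either way.
- **Permutation comparisons** use a 1e-12 slack when counting
  `|ρ_perm| ≥ |ρ_obs|` so floating-point ties are counted as ties.
- **Population split**: steps are counted on the tree's leaves, ranking on
  the full matrix. When a supplied tree covers only a subset of the matrix
  taxa (the empirical design: a sequenced subsample inside a larger key),
  that is allowed and the report flags `populations_differ`. When one
  simulated matrix serves both analyses, a character invariant on the tree
  is also unusable for ranking and is excluded from the correlation —
  which is why `n_analyzed` can be below `n_characters`.
- **Problem sizes in tests**: the oracle-equivalence checks run on
  exhaustive enumerations over trees of up to 7 leaves and thousands of
  random characters; the replicated correlation study uses 20 seeds of
  100-taxon, 47-character simulations with 500 Monte-Carlo permutations
  each; the acceptance script runs a single 350-taxon study with 100,000
  permutations. These sizes keep the whole suite in well under a minute of
  compute per heavy test while leaving the statistics comfortably
  diagnostic.

## Known limitations

- The Best score is this package's normative definition of the evenness
  principle, not a reimplementation of any proprietary ranking; absolute
  score values are not comparable to commercial software, only orderings.
- No ordered or cost-matrix characters; no correlated character evolution;
  no rate variation along branches.
- The simulator's missingness model (MCAR) and class tags (round-robin)
  carry no biological signal; per-class contrasts in simulated data test
  the machinery, not biology.
- Exact permutation p-values are limited to n ≤ 9 by factorial growth;
  beyond that the Monte-Carlo estimator's resolution is `1/(n_perm + 1)`.
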