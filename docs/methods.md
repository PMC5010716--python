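# Methods

This note documents the statistical models behind `p53conv`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for reproducing a
result.

## Distances

Per-domain sequence distances use the Poisson correction
`d = −ln(1 − p)`, where `p` is the proportion of differing sites among
comparable sites of two equal-length, gap-free fragments. The correction
is the exact inverse of the expected visible-difference fraction when
substitutions arrive as a Poisson process with all sites equally mutable
and all replacements equally likely — the 20-state equal-rates model. It
under-corrects multiple hits under rate heterogeneity or biased exchange
matrices; gamma or matrix-based (JTT/WAG) distances are deliberately out
of scope, since every statistic downstream consumes only the *ranks* of
the distances and is insensitive to monotone re-scalings.

Conventions:

* Sites where either residue is not one of the 20 standard amino acids
  (gaps, X/B/Z) are missing. The default `complete` deletion removes such
  sites for the whole fragment set before any pair is scored, so all
  pairs share one site set (a no-op on fully standard fragments);
  `pairwise` deletion excludes them pair by pair. Both are offered
  because distance tools commonly support both and analyses should be
  reproducible under either.
* `p = 1` (all sites differ) raises an error naming the offending pair
  rather than returning infinity: rank statistics cannot order infinities
  meaningfully, and a saturated short domain is a data problem the user
  must see. The simulation-study helpers (below) instead record and skip
  such replicates, which at the default divergence occur with probability
  ~1e-5 per deep pair.
* Divergence-time matrices come from newick branch-length path sums
  (dendropy) or a pairwise TSV; ultrametric inputs are checked with the
  three-point condition at tolerance 1e-9.

## The intra-group similarity U test

Two groups of k₁ and k₂ species yield distance vectors S₁, S₂ of
n = k(k−1)/2 intra-group pairwise distances each. The statistic
`U = #{(a,b): S₁[a] > S₂[b]}` has null expectation `EU = n₁n₂/2`. Small U
means the first group is internally more similar — the convergence
alternative — so all one-sided p-values in this package are lower-tail.

The n distances per group are metrically dependent (d_ij and d_jk
constrain d_ik), which breaks the independence assumption of the
Mann–Whitney null. Three nulls are reported side by side:

* **Exact** — the no-ties rank-count recursion
  `N(u; n₁, n₂) = N(u−n₂; n₁−1, n₂) + N(u; n₁, n₂−1)`, normalized by
  `C(n₁+n₂, n₁)`; exact under independence, reported for comparability
  with standard practice.
* **Normal** — the usual large-sample approximation with tie-corrected
  variance and optional continuity correction.
* **Monte-Carlo geometric null** — per run, k₁+k₂ i.i.d. uniform points
  in `[0,1]^dim`; the two intra-group Euclidean distance vectors give one
  U draw. The point configuration induces exactly the kind of metric
  dependence the data have, so the null U distribution is wider than the
  independent-sample one (sd ≈ 16.8 at k=5, dim=2, versus 13.2
  independent). The p-value is the plain proportion of runs at or below
  the observed U (a `(r+1)/(N+1)` pseudo-count variant is available when
  a never-zero p is needed). Default `N = 100,000` runs.

Numerical conventions and open choices:

* **Hypercube dimension.** The geometric null needs a dimension for its
  point space; nothing in the data pins it down. The default is
  `dim = 2`. Sensitivity is modest and monotone: the null sd of U at
  k₁=k₂=5 is 15.7 (dim 1), 16.8 (dim 2), 17.2 (dim 3), 17.7 (dim 10), so
  dim 2-3 matches the dependence of small point configurations well; the
  option `mc_dim` exposes it.
* **Tie rule.** `strict` counts only strict inequalities (U is then not
  complement-symmetric under ties); `half` adds 0.5 per tie. Default is
  strict — the definition the headline statistic uses — with `half`
  available because discrete distances from short domains tie often. The
  exact p-value refuses half-integer U (its null has no ties); the driver
  reports NaN there and the normal/Monte-Carlo columns remain.
* **FDR.** Benjamini–Hochberg step-up across domains, excluding the
  divergence-time control column (it is a control, not a hypothesis).
* **One p-value convention.** The Monte-Carlo tail is taken on the side
  of the stated alternative (smaller group-1 distances ⇒ lower tail). A
  symmetric two-sided variant (`|U − EU| ≥ |U_obs − EU|`) is provided.

## Motif grammar and enrichment

A gapped motif is a token string: fixed residue, wildcard `X`, or residue
class `[DE]`. Matching is anywhere-in-fragment, overlapping matches
included; composite patterns require every motif to match, by default at
strictly increasing start positions (N- to C-terminal), overlaps
permitted. Anywhere-in-domain scanning (rather than anchoring to
homologous alignment columns) is the robust choice for short disordered
domains where alignments are least reliable; a position window can be
emulated by scanning a sliced fragment.

Enrichment uses exact tests throughout, since group sizes are tens:

* 2×2 Fisher with an optional noncentral null: the tested cell follows
  Fisher's noncentral hypergeometric distribution with odds ratio
  `null_or` (scipy's `nchypergeom_fisher`; the central hypergeometric at
  `null_or = 1`). Two-sided p sums outcomes with point probability ≤ the
  observed one (relative tolerance 1e-12 for ties). A zero margin yields
  p = 1 with a warning. The greater-tail p is strictly increasing in
  `null_or` (the family is stochastically increasing in the odds ratio).
* 2×3 Freeman–Halton by full margin-constrained enumeration of first-row
  compositions (bounded at table total 200; the designs this serves are
  under 50).
* The screening flag marks patterns with p < 0.005 in the primary
  comparison — the threshold used to select patterns for re-testing in a
  balanced design, configurable.

## Reference-species similarity

Given a reference species from the tolerant group, the *expected* 2×2
table classifies tolerant/sensitive species as phylogenetically close or
distant (by clade list, e.g. Rodentia/Lagomorpha, or by a divergence-time
threshold; both supported, clade list primary for real data). The
*observed* table keeps the same number of close slots but fills them with
the species nearest to the reference by domain distance; boundary ties
break lexicographically by species id (deterministic) and are flagged.
Because the expected composition is itself skewed, the Fisher test on the
observed table runs against the noncentral null with
`null_or = (H_close/H_dist)/(S_close/S_dist)` from the expected table. If
a zero cell would degenerate the odds ratio, a Haldane–Anscombe +0.5 is
applied to all four cells *only* inside the odds-ratio computation, never
to the counts. Sidedness defaults to two-sided, with one-sided options.

Note on calibration: under a no-convergence null this exact test is
conservative, not uniform — the same phylogeny that defines the expected
table drives the domain distances, so the observed composition
concentrates near the expected one. The test suite asserts validity
(empirical level ≤ nominal), which is the property the test actually has.

Jackknife-style stability: the test is repeated on seeded random
subsamples without replacement at fixed sizes (the reference always
retained), and the mean p per size is reported with the count of
replicates skipped because a subsample emptied a group or the close set.

## The synthetic-data generator

The generator produces the study design the statistics target, with exact
ground truth:

* **Tree.** A caterpillar of HT/HS cherries — each tolerant species
  paired with a sensitive sister, every pair with its own last common
  ancestor. Time unit: 100 My. Defaults: 5 pairs, cherry depth 0.1, and
  backbone joins compressed between 0.9 and 0.99 — a rapid radiation,
  mirroring the near-simultaneous placental interordinal splits.
  Compressed joins keep baseline cross-pair divergence homogeneous, so
  detection power reflects the implanted signal rather than depth
  heterogeneity.
* **Sequences.** 20-state equal-rates evolution (uniform root, per-branch
  substitution probability `1 − exp(−rate·b)`, replacement uniform over
  the other 19 residues, sites independent, gap-free). Default rate 0.5
  substitutions/site per unit time: cross-pair p-distances ≈ 0.6, the
  regime of rapidly evolving disordered regions over deep mammalian
  comparisons. Two 21-site domains by default (one implanted, one
  control), matching the length of a short transactivation subdomain.
* **Implantation.** With probability π per tolerant taxon, a window of
  the target domain is overwritten with a motif realization: fixed tokens
  literally, class tokens sampled per carrier, wildcards left as evolved.
  Overwriting (rather than mutating toward the motif) gives an exact
  carrier record and makes π and motif length the only effect-size knobs.
  The default implant is the fully specified pentapeptide DLLAT (a
  realization of a `[DE]LLX[ST]`-style signature): a convergent event
  fixes identical residues; wildcards belong to the scanning grammar.
* **Reference studies.** In the reference-similarity experiments the
  reference species is implanted unconditionally and π applies to the
  remaining tolerant taxa — the reference is the study organism whose
  motif is being tested, so it carries it by construction. (Without this,
  enrichment is genuinely non-monotone at small π: overwriting a carrier
  moves it *away* from a non-carrier reference, because the fixed residues
  replace residues partially shared by descent.) The reference study uses
  a larger population — 16 pairs with joins spread 0.9–1.4 and rate 0.3 —
  so that a divergence-time threshold (default 2.3) yields graded
  close/distant sets of useful size.

What the generator does **not** emulate: indels and alignment error
(sequences are gap-free), rate variation across sites and lineages,
biased amino-acid exchangeabilities, non-ultrametric trees, and
correlated implantation (carriers are independent given π). Passing tests
therefore show that the statistics behave as designed under the idealized
model that motivates them — not that real alignments are free of the
confounders (alignment artefacts, compositional bias) that the package's
controls (divergence-time column, balanced pairs) only partially address.

## Operating characteristics (computed by tests and `scripts/acceptance.py`)

Under the default study conditions (5 pairs, 21-site domains, strict
ties, dim-2 null, α = 0.05), the suite verifies: the type-I error of the
Monte-Carlo U test over 2,000 null replicates lies in [0.03, 0.07]
(slightly conservative, reflecting tie discreteness); power at π = 1 over
200 replicates is ≥ 0.9 while the un-implanted control domain rejects in
≤ 10%; and in the reference study the mean count of tolerant species
among the sequence-close set increases strictly with
π ∈ {0, 0.25, 0.5, 0.75, 1}.

Problem sizes used by the default test run and the acceptance script —
2,000 null and 200 power replicates, Monte-Carlo nulls of 20,000–100,000
runs, 10,000 random sequences for the motif-scanner oracle, exhaustive
Mann–Whitney enumeration to n₁ = n₂ = 6, Freeman–Halton enumeration to
table total 15 — were chosen so the full suite completes in well under a
minute while leaving the binomial error of every estimated rate small
relative to its acceptance band.

## Known limitations

* The exact Mann–Whitney column is valid only under independence; it is
  reported because it is the field's standard reference point, and it is
  anti-conservative relative to the geometric null (whose U variance is
  larger). Conclusions should rest on the Monte-Carlo column.
* The geometric null fixes the dependence structure by construction
  (uniform points in a hypercube); real distance matrices may be more or
  less constrained. The dim option is a sensitivity knob, not a fit.
* Exact conditional tests on small tables are discrete; p-values are
  conservative near nominal levels and FDR adjustment inherits that.
* The domain map defaults (human p53 coordinates TAD1 1–40, TAD2 41–61,
  PRD 64–92, DBD 94–312, NLS 316–325, TD/RD 323–393) follow standard
  annotation; boundary conventions differ across sources, so any serious
  analysis should pass its own map (`domain.NAME = START-END` lines).
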