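# Methods

## The selection probabilistic model

A multi-round selection experiment is modelled generatively.  Let `q_0` be
the sequence distribution of the input pool and `q_r` the distribution after
round `r`.  Each round applies a selection factor and renormalizes,

    q_r(x) = q_{r-1}(x) · exp(f_r(x)) / Z_r ,

and the observed read counts of round `r` are a draw from
`Multinomial(N_r, q_r)` at the sequencing depth `N_r`.  The per-round fitness
is the log selection factor.  It is parametrized through a shared trunk,

    f_r(x) = a_r · g_θ(x) + b_r ,      a_r = softplus(ρ_r) ≥ 0 ,

where `g_θ` is a fully connected ReLU network (defaults: 4 hidden layers x
100 units, dropout 0.1, weight decay 1e-5, Adam at learning rate 1e-3) on a
one-hot encoding of the concatenated library sequence.  The affine-head
coupling is the minimal structure under which both per-round fitnesses and a
single *global* fitness `g_θ` are well defined; the non-negativity of `a_r`
encodes that selection strength cannot invert sign between rounds.

Two identifiability facts shape the implementation and are tested:

- **Gauge freedom.** `b_r` cancels in the normalized `q_r`, and adding a
  constant to `g_θ` changes nothing; reported scores therefore fix the gauge
  by zero mean over the training universe.  Absolute fitness values are
  dataset- and gauge-dependent and are never interpreted; only differences,
  ranks and derived geometry are.
- **Chain collapse.** With model-propagated rounds the recursion telescopes:
  `q_r ∝ q_0 · exp(A_r g_θ)` with `A_r = a_1 + … + a_r`.  The trainer uses
  this closed form for an exact full-likelihood gradient (no minibatch
  approximation of the normalizing constants); `q_0` is the additively
  smoothed (pseudo-count 0.5) round-0 empirical distribution.  A plug-in
  variant, where `q_{r-1}` is replaced by the previous round's smoothed
  empirical frequencies, is available via `SPMFitConfig(propagation="plugin")`
  for debugging.

Training is full-batch over the observed universe (the normalizers couple
all sequences); scoring chunks its forward passes by `batch_size`.  Early
stopping monitors the count MSE on a held-out 10 % of final-round sequences
(`val_fraction=0`, e.g. for tiny toys, disables it and relies on
`max_epochs`).  Hyperparameter selection uses k-fold cross-validation on the
final round only, always training on all earlier rounds, scored by MSE
between expected counts `N_R·q_R(x)` and held-out observations.  The network
and optimizer are implemented directly on numpy arrays; the reference scale
is CPU minutes on reduced schemes, not GPU-scale universes.

## Synthetic data generator

The generator is the package's ground-truth oracle and emulates the study
conditions: a two-chain library (default reduced scheme: 3 + 3 positions,
DTS alphabet {M,F,L,I,V}, 15,625 sequences — small enough for exhaustive
verification; the full 5+6-position scheme is supported), five positive
selection rounds after the unselected round 0, and 1e5 reads per round.  The
true fitness is additive-plus-pairwise: per-position effects N(0, 1.0²), a
fraction 0.3 of position pairs carrying N(0, 0.5²) interaction tables, half
of the chosen pairs spanning the two chains.  These scales put pairwise
epistasis at a realistic minority share of fitness variance while keeping it
detectable at the stated depth.  Nature's selection link is unknown; a
logistic link `s_r(x) = σ(stringency·(f(x) − offset))` is used because it
keeps selection probabilities in [0, 1].  The offset defaults to the mean
true fitness so selection is informative from round 1.

The generator matches the SPM's likelihood family by construction, so model
fitting on simulated data is a well-posed parameter-recovery experiment.  It
deliberately omits sequencing error, PCR bias and cell-growth dynamics:
passing recovery tests demonstrate correct inference under the modelled
generative process, not robustness to those real-data artefacts.

## Enrichment and sequence similarity networks

Pair enrichment uses the one-sided hypergeometric test: with `M` total
final-round reads, `n` reads of a given A chain, `N` of a given B chain and
`k` observed co-occurrences, `p = P(X ≥ k)` computed as the survival
function at `k − 1` (scipy's exact log-space implementation; verified
against direct pmf enumeration to 1e-12 relative for `M ≤ 200`).  Retention
is `p < 0.05` (strict) and `k ≥ 20`; no multiple-testing correction is
applied by default, matching the raw-p filtering convention of this assay.

Library sequences are fixed-length position strings, so the network's "edit
distance" is Hamming distance (indels are meaningless); an edge joins
sequences at distance strictly below the threshold (threshold 3 connects
sequences differing at ≤ 2 positions).  Communities default to greedy
modularity maximization (deterministic); Leiden via igraph is available by
option.  Community labels are stabilized by ordering communities by size,
then lexicographically.

## Epistasis decomposition

Functional ANOVA under the uniform reference distribution over the alphabet
(the orthogonal basis underlying the Walsh–Hadamard view of a landscape):

    β_∅        = E[f]
    β_i(a)     = E[f | x_i = a] − β_∅
    β_ij(a,b)  = E[f | x_i = a, x_j = b] − β_i(a) − β_j(b) − β_∅

with Möbius subtraction for higher orders (default max order 2, supported to
any order; cost grows combinatorially).  Conditional means are exhaustive
when the enumerated space is at most `exhaustive_limit` (default 1e6)
sequences and Monte Carlo (1e5 uniform draws, fixed seed) otherwise.  A
term's **importance** is max − min of its effect sizes over letter
configurations — the maximal fitness swing achievable at those positions; a
variance-based importance was deliberately not used because the max-minus-min
dynamic range is the quantity the downstream contact-ratio comparison needs.
**REI** (per order) is mean inter-chain importance per term / mean
intra-chain importance per term; it is reported as undefined when the
denominator is numerically zero (≤ 1e-9, absorbing float round-off on
exactly additive landscapes).  A frequency-weighted reference distribution is
a possible variant but non-default: the uniform reference keeps contrasts
orthogonal and the reconstruction identity exact.

The decomposition consumes any scorer.  External score tables (e.g.
structure-conditioned sequence scores) are decomposed identically; exhaustive
mode requires full coverage of the enumerated space and reports missing
sequences otherwise.

## Adaptive walks and landscape geometry

A trajectory starts at a sequence (uniform over the full combinatorial
space by default — start restriction to observed sequences is possible but
not the default, since walks are meant to probe the whole landscape) and
repeatedly takes one uniformly chosen single-position substitution among
those that *strictly* increase fitness, terminating at a local optimum.
Ties are not improving moves (exact float comparison; ties are measure-zero
for learned landscapes but possible with quantized scorers).  Accessibility
of a sequence is the fraction of walks terminating there.

For enumerable spaces the simulator precomputes the improving-neighbor table
and advances all walks in lockstep (vectorized); larger spaces fall back to
a lazy memoized walker with identical semantics.  Visit tracking stores, per
visited sequence, the number of walks through it ending at each terminal —
a path visits each sequence at most once because fitness strictly increases
— which is exactly the sufficient statistic for the seed metrics, avoiding
storage of millions of full paths.

Energy is negative fitness.  A well is a terminal sequence; relative energy
subtracts the minimum energy among all terminals found.  Well **depth** is
the minimal *cumulative* uphill barrier from its representative to any other
top-k representative (default k = 20): edge weight `max(0, E(v) − E(u))` on
the implicit single-substitution graph, minimized by Dijkstra with early
stop once all other representatives are settled.  "Cumulative" (sum of
positive increments) is the implemented reading; a max-single-barrier mode
is available by flag for sensitivity analysis.  Both costs are monotone
along paths, so Dijkstra is exact for either.

Landscape comparison bootstraps the full pipeline: resample read counts
(multinomial per round, totals preserved), refit the SPM, re-simulate walks,
recompute top-well depth and accessibility, then test
`natural > factor × synthetic` by a one-sided Mann–Whitney U (defaults:
factor 3 for depth, 5 for accessibility).  The samples are unpaired — the
test itself is unpaired, and pairing bootstrap replicates across two
independent datasets has no natural correspondence.  Dissociation constants
convert to energy gaps by `ΔΔG = RT·ln(K_D2/K_D1)` with
R = 1.987e-3 kcal/(mol·K), T = 298 K by default.

## Seed sequences and paths

For a weak-binding sequence `s` and well `w`: exclusivity = (walks through
`s` ending at `w`) / (walks through `s`); contribution = (walks through `s`
ending at `w`) / (walks ending at `w`).  Seeds must lie in a fitness band
(on selection data: the mean inferred fitness of sequences with final-round
read count 5 and 20 — computed from the dataset, never hard-coded, because
the band is dataset- and gauge-specific), satisfy exclusivity ≥ 0.9 and
contribution ≥ 0.01 toward their most-likely target well, and sit at least
3 substitutions from it.  The most-likely well is the one receiving the
largest share of the sequence's through-traffic among the candidate target
wells; when the modal well over *all* terminals differs, the candidate is
flagged rather than dropped (the two notions can disagree and both are
reported).

Paths from a seed are extracted by re-simulating a dedicated ensemble
started at the seed — exact for the seed's downstream behaviour and far
cheaper than storing global paths.  Distinct step chains are tallied by
multiplicity; the maximal smallest-weight tail of the path distribution
whose collective share stays below the minor threshold (default 0.15) is
folded into a single minor fraction.  (A per-path reading of "minor" is the
other defensible convention; the collective reading was chosen so that the
reported major paths always cover at least 1 − threshold of the traffic.)

## Structure contacts

Contacts are heavy-atom pairs across two chains at distance strictly below
the cutoff (default 4.0 Å atomic; a 3.8 Å convention common for
residue-level curation is available), first model only, altloc A only,
waters/ligands excluded.  Residues are labelled library or framework by the
scheme's randomized position lists; contacts are then LL, LF_A, LF_B or FF,
and the contact ratio is LL/(LF_A + LF_B), undefined when no LF contact
exists.  Residue-level summaries derive from atomic contacts (a residue pair
is in contact if ≥ 1 atomic contact).

## Numerical and scale choices

- All randomness flows from integer seeds through numpy's PCG64 generator;
  pipeline stages derive their seeds deterministically from the master seed
  and stage name (all below 2^31).  Fixed seed + fixed config ⇒ identical
  output.
- Reference desk scales: the recovery benchmark uses the 6-position scheme
  (15,625 sequences), 5 rounds x 1e5 reads, 200 training epochs; walk
  ensembles of 1e5–2e5; bootstrap counts of order 10–20.  The pipeline's
  defaults keep the larger canonical values (1e7 trajectories, B = 1000,
  k = 20 wells) for production runs on real datasets.
- Degenerate-codon stop codons are reported, never silently dropped, and
  excluded from protein diversity.
- Dataset invariants (per-round totals, alphabet validation) are enforced at
  construction; duplicate count rows are summed on load.

## Known limitations

- The affine-head parametrization of per-round fitness is one defensible
  coupling between round-specific and global fitness, not the only one; REI
  trends across rounds inherit this choice.
- The generator's logistic selection link is an assumption; the SPM itself
  is link-agnostic (it learns `f_r` directly), but simulated-data recovery
  statements are relative to this link.
- Monte-Carlo epistasis estimates are unbiased but noisy for high-order
  terms; exhaustive mode should be preferred whenever the space allows.
- Walk ensembles estimate accessibility with binomial error ~sqrt(a(1−a)/n);
  conclusions about wells with accessibility below ~10/n are unreliable.
- The structure stage classifies contacts only; buried surface area, shape
  complementarity and related interface metrics are out of scope.
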