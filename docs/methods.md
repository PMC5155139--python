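# Methods

This note documents the models implemented in `paleobite`, the
assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generators do and do not emulate.

## Allometric estimation

Craniodental predictors (total skull length, molar-row lengths) relate
to body mass as power laws, so all models are ordinary least squares of
log₁₀(response) on log₁₀(predictor). Logs are base 10 throughout, and
rounding happens only at the reporting layer (masses to 1 decimal,
RPS to 2 decimals, forces to integer newtons); internal values keep
full precision.

*Back-transformation bias.* Exponentiating a log-scale prediction
estimates the conditional median, not the mean. The ratio estimator
RE = Σy / Σŷ over the training set (with ŷ the back-transformed fitted
values) is stored with each model and multiplies every prediction. On
the training set this makes Σy = RE·Σŷ an exact identity; for noise-free
power-law data RE = 1.

*Uncertainty.* Two interval rules coexist deliberately. Body-mass
estimates use the multiplicative prediction-error rule
point × (1 ∓ PE), where PE is the published prediction-error fraction of
the source regression (e.g. 0.14); this is the rule that reproduces
published mass ranges exactly at 1-decimal rounding. Prey-size
extrapolations instead use the regression's own 95% prediction interval
computed on the log scale (t-quantile × standard error of a new
observation) and back-transformed, which is asymmetric on the
arithmetic scale and collapses to the point as residual variance
vanishes. We treat the interval as a prediction interval (new
observation) rather than a confidence interval on the mean, since the
scientific question is the size of one prey item, not the average.

*Predictor preference.* When several predictors are available for one
specimen, the one with the smallest PE wins (e.g. a 14% molar-row model
over a 19% skull-length model). Incomplete skulls are scaled to a
complete reference specimen by simple proportionality on a shared snout
segment before entering the skull-length model.

*Coefficients.* No published regression coefficients are distributed
with the package. `paleobite.coefficients` ships synthetic placeholder
blocks, labelled as such, so pipelines run end to end; real analyses
must supply their own coefficients or refit from a training table.

## Bite mechanics

The dry-skull lever model treats the adducted jaw as a static lever
about the temporomandibular joint. Assumptions: muscle force is
proportional to projected cross-sectional area at a constant muscle
stress of 300 kPa (the conventional mammalian value; configurable);
each muscle group acts as a single force vector perpendicular to its
measurement plane through the area centroid; measurements from one side
are doubled for bilateral symmetry. The 2-D projection geometry that
produces areas and lever arms is upstream of this package — areas and
arms enter as numbers.

BFQ is recomputed from whichever comparative (mass, force) table is
supplied, not from frozen published coefficients, so values shift
slightly with the table; that is a property of the statistic, not a
bug. The geometric mean of training-set BFQs is exactly 100 because OLS
residuals sum to zero in log space — the test suite asserts this to
0.1%. When several body-mass estimates exist for a query taxon the
pipeline defaults to the **largest** (conservative, since smaller
masses inflate BFQ) and logs the choice. The query taxon is not part of
the comparative regression unless the user puts it there.

Beam theory treats teeth and mandibular corpora as solid ellipses using
outer diameters (no pulp-cavity correction, matching standard
comparative practice). Section modulus about the axis perpendicular to
bending is Z = π·d_perp·d_bend²/32; canine bending strengths divide by
crown height, mandibular profiles by the distance from each interdental
gap to the condyle. The six-gap anterior→posterior order (canine,
p2–p3, p3–m1, m1–m2, m2–3, post m4) follows the metatherian dental
formula and is enforced on input. No normalization by body size is
applied before bivariate comparison; callers can normalize externally.

## Dental microwear

Counts of nine feature classes over a fixed 0.3 mm² field at ×70 are
normalized to percentages per specimen, making profiles invariant to
counting effort. Specimens with zero counts or a taphonomic-damage flag
are excluded with a logged reason — damage screening is an input flag,
not an image-analysis step. Tooth-position information is metadata
only.

The dissimilarity default is Bray–Curtis on percentage profiles —
appropriate for zero-inflated compositional data and the
community-ecology lineage of the toolchain — with Euclidean available;
the choice is logged. PCoA uses Gower double-centering of −½D² and an
eigendecomposition; coordinates are eigenvectors scaled by √λ over
positive eigenvalues. Negative eigenvalues (expected under Bray–Curtis)
are retained and reported as a summed magnitude, with no Cailliez
correction by default; proportions of variance are computed over
positive eigenvalues only. New specimens are projected with the
standard Gower add-a-point formula, which reproduces training
coordinates exactly. For Euclidean input, PCoA coordinates equal PCA
scores up to axis sign (asserted to 1e−8 in the tests).

Diet classification is a k-nearest-neighbour vote (default k = 5) in
the ordination space; ties are reported in full, never silently broken,
because real fossils often straddle guilds. Intra-observer error uses
Spearman's rank correlation on paired recounts, reported for total
features and separately for small pits and cross scratches (the
dominant pit and scratch classes).

## Maximum parsimony

Tree lengths come from generalized (Sankoff) dynamic programming,
vectorized across characters: unit step costs for unordered characters,
|i−j| for ordered (additive) ones. Missing cells (`?`, and `-`, which
is treated identically) cost nothing anywhere; polymorphic cells
contribute their cheapest member state; polytomies are scored directly
by the multifurcating recursion, adding no resolution penalty. Internal
states beyond a character's observed range are admitted but can never
lower the minimum (both cost functions are metrics). The scorer is
validated against exhaustive minimization over all internal-state
assignments on hundreds of random small instances, and against an
independent Fitch implementation.

Per-character bounds: the minimum m is the smallest number of states
that can cover every cell minus one (unordered; found by subset search)
or the width of the shortest interval meeting every cell (ordered); the
maximum g is the star-tree value, n − (largest state frequency) for
unordered and the minimized sum of absolute deviations from an integer
median for ordered. CI = Σm/Σs and RI = (Σg−Σs)/(Σg−Σm), with
parsimony-uninformative characters (g = m) excluded from the RI sums
and CI defined as 1 when a tree implies zero steps.

Search is the classic two-stage heuristic: random-addition Wagner
starting trees, then steepest-descent SPR followed by TBR, per
replicate, deterministic given the seed. All distinct trees at the best
length are retained, including equal-length trees reached by walking
plateaus with SPR moves (capped, default 500 trees). Specialized
metaheuristics (ratchet, sectorial searches, tree fusing) are out of
scope: on matrices of the sizes treated here the optimum is reachable
with replicated SPR/TBR, and the optimum — not the route to it — is
what downstream statistics consume.

Bremer decay per strict-consensus clade is the length of the best tree
lacking the clade minus the optimal length. With ≤ 9 taxa every
topology is enumerated and the decay is exact; above that, suboptimal
trees within a window (default 3–5 steps) are retained during search
and clades unbroken inside the window report "> window" (∞ in the
machine-readable output) rather than a fabricated number.

The Templeton test drops characters with equal steps on both trees,
ranks the remaining step differences by absolute value (average ranks
on ties), and computes a two-sided Wilcoxon signed-rank p. With ≤ 25
nonzero differences the null is enumerated exactly by convolving the
rank-sum distribution over sign assignments — valid with tied ranks,
where textbook tables and some library "exact" modes are not — and a
normal approximation with continuity and tie corrections is used
beyond. Swapping the trees negates the statistic and preserves p.

Synapomorphy maps require a rooted tree. One most-parsimonious
ancestral reconstruction is chosen by Sankoff backtracking with an
explicit tie rule — ACCTRAN by default (prefer the state differing from
the parent, placing changes early), DELTRAN available; residual ties go
to the smallest state and are flagged ambiguous. The mapped steps sum
exactly to the tree length.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their parameters and an explicit
seed (numpy `default_rng`; no global state). Defaults mirror the scales
of a small-bodied Cretaceous predator study: masses 0.1–300 kg
(log-uniform), skulls of order 10 cm, nine microwear features in five
dietary guilds of ~8 specimens, and 12-taxon, 50-character matrices —
miniature versions of a 48-taxon, 164-character analysis, sized so the
full test suite runs in about a minute.

- `simulate_allometric_table`: exact power law plus lognormal scatter
  (default σ = 0.1, n = 200). Emulates regression training sets; does
  not emulate phylogenetic autocorrelation, so recovery tests say
  nothing about PGLS-style corrections, which are out of scope.
- `simulate_skull_fixture`: plausible lever geometries with the
  analytic bite force recorded alongside; can invert the lever formula
  to hit a target force exactly, which exercises the reporting path at
  a realistic magnitude.
- `simulate_microwear_guilds`: Dirichlet–multinomial counts (default
  total 120 per specimen) around guild concentration vectors encoding
  the field's expectations — pit/puncture-dominated carnivores through
  scratch-dominated herbivores. Real microwear adds inter-observer
  effects and taphonomic noise that the generator does not model, so
  classification accuracy here is an upper bound on real data.
- `simulate_character_matrix`: Mk-style evolution (uniform jump to a
  different state with probability (1−e^(−rt))·(k−1)/k; ordered
  characters take ±1 reflected steps via a Poisson number of events) on
  a given or simulated tree, with optional missing-data and
  polymorphism masking. Defaults (3 states, rate 0.5) produce the
  moderate homoplasy typical of morphological matrices (CI ≈ 0.5 on
  12-taxon runs). It does not model correlated characters, ascertainment
  bias against constant characters, or rate heterogeneity.
- `simulate_strong_signal_matrix`: the recovery regime — long internal
  branches (1.0) and short terminals (0.05) so change concentrates on
  internal edges as clade-marking synapomorphies, with 10-state
  characters at rate 0.35 keeping same-state convergence rare. This
  regime was designed from first principles (terminal autapomorphies
  are harmless; internal-edge collisions are what destroy recovery) and
  is the appropriate ground for "does search recover the truth" tests.
  Even here, exact length ties between the true topology and a
  one-rearrangement neighbour occur in a minority of simulations;
  passing recovery tests therefore demonstrates correct behaviour of
  the search, not a guarantee for arbitrary data.

## Numerical and interface choices

- State sets use ≤ 10 integer states (0–9), matching both matrix
  formats' single-character cells.
- Newick I/O preserves labels with spaces or apostrophes by
  single-quoting ('' escaping), so museum-style names (e.g. a quoted
  skull nickname) round-trip.
- Strict consensus builds from the intersection of canonical splits;
  it is idempotent and order-independent.
- Distance-matrix validation (symmetry, zero diagonal) is strict;
  asymmetric input is an error, not a warning.
- Degenerate inputs fail loudly with domain-specific messages: zero
  out-levers, non-positive allometric data, comparative tables with no
  mass spread, k larger than the reference set.
- Every stochastic operation takes a seed; pipeline runs log inputs,
  parameters and choices so reported numbers are traceable.

## Known limitations

- No finite-element analysis, muscle-architecture (pennation)
  corrections, or 3-D geometry: the lever and beam models are the
  classical 2-D abstractions.
- No likelihood or Bayesian morphology models, implied weighting, or
  resampling supports; parsimony only.
- Heuristic Bremer values above the exhaustive threshold are upper
  bounds conditional on the retention window.
- The shipped allometric coefficients are placeholders; all biological
  conclusions require user-supplied training data.
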