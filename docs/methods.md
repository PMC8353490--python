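# Methods

This note records the models, numerical choices and open design decisions
behind `clonedyn`, in the order data flow through the pipeline. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic world

The generator (`clonedyn.synthetic`) emulates a barcoded stem-cell culture:
`n_lineages` founders (default 2,560, the scale of a tracked experiment),
each expanded to `initial_cells_per_lineage` cells (default 1,000; a
`("lognormal", mean, sigma)` spec is available for skewed clone sizes),
distributed over three states (default 90:5:5, the sorted composition) and
evolved over sampling days 0, 6, 12, 18, 24.

Per 6-day interval, three dynamics are available:

- **markov** — each cell independently draws its next state from its row of
  the transition matrix (vectorized multinomials per source state);
- **coordinated** — with probability `coordination_prob` (default 0.5) a
  lineage moves as a block: one target state is drawn from the *plurality*
  state's matrix row and a Binomial(`coordination_strength`, default 0.8)
  fraction of every cell moves there together. The block-move mechanics are
  a design choice — only the contrast between memoryless and kin-coordinated
  outcomes is externally specified — chosen because it reproduces
  corner-seeking lineage trajectories;
- **mixed** — a `mixed_fraction` of lineages is coordinated-capable
  (assigned once, so the trait is persistent per lineage), the rest purely
  Markovian. Persistence matters: because coordination events are drawn
  independently each interval, *pure* coordinated mode has no lineage-level
  memory of motility, and history-persistence properties are therefore
  exercised in mixed mode.

The default transition matrix is `a·I + (1−a)·1·π` with persistence
`a = 0.5` and `π = (0.73, 0.15, 0.12)`; any `a ∈ [0,1)` leaves `π`
stationary, so the long-run composition matches the steady state used by
the entropy statistic. Growth is a 3×3 factor per transition type
(default 1 everywhere: observed lineage-size distributions are stable over
the course); grown counts are stochastically rounded (floor + Bernoulli on
the fractional part) to stay unbiased at small counts. Sorting is binomial
thinning at `sort_fraction` (default 0.5 — half the culture is sorted).

Reads are 129-nt amplicons: 30-nt barcode, 65-nt constant region, 10-nt
sample index, 24-nt terminal constant region. The printed reference's
terminal segment is 24 nt even though its stated span (nt 106–130) would be
25; the printed sequence wins. Barcodes are uniform ACGT with a pairwise
Hamming floor of 7 (so distance-<6 collapsing can never merge two true
lineages); the weak/strong alternating alphabet of the ClonTracer library
is deliberately not reproduced — it adds nothing to test power. Substitution
errors are independent per base; qualities come from a pluggable model
(constant Q40 default, truncated-Gaussian alternative), Phred+33 capped at
40.

What the generator does *not* model: lentiviral multiplicity of infection,
PCR duplicates and chimeras, paired-end reads, depth-dependent variance,
intermediate (ungated) cell states, and culture-split losses between
sampling days. A green round-trip test therefore establishes that the
informatics is lossless and correctly thresholded, not that these
wet-lab artifacts are handled.

## Read filtering and collapsing

A read passes iff (1) summed barcode-region Phred > 960 (80% of the 1,200
maximum; strict inequality, so exactly 960 fails), (2) Hamming distance to
constant region 1 < 6, (3) Hamming to constant region 2 < 3, and (4)
Hamming between its index segment and some sample index < 2, which also
demultiplexes it. Reads shorter than 129 nt fail rather than being padded.
Sample indices must be pairwise Hamming ≥ 3 so criterion 4 cannot be
ambiguous.

"Barcodes less than 6 mismatches apart are collapsed" is a relation, not an
algorithm (the relation is not transitive). The implementation is
abundance-ranked greedy centroid clustering: visit barcodes in descending
pooled-read order; merge into the first-found nearest centroid at distance
≤ 5, else found a new centroid. Collapsing runs on the pooled table so a
barcode maps to one centroid across all samples (per-sample collapsing
could split a lineage's identity between samples). Per-sample read totals
are conserved; the operation is idempotent; a brute-force reimplementation
serves as the oracle in tests.

## Normalization

Read counts are converted to cell numbers by fixing each state sample's
total: 90/5/5 million (the 90:5:5 sorted composition of 10⁸ cells) by
default; CD24-high/low samples to 3/1 million (actually sorted numbers).
The Markov-test scheme fixes 10⁶ cells per timepoint; only the total is
externally specified, so the split is realized as 900,000/50,000/50,000 —
the same 90:5:5 ratio — with floor rounding, which reproduces the
round-down-to-zero attrition that removes small lineages from the testable
set. Rounding is applied only where the original procedure applies it (the
Markov test); growth estimation uses unrounded cells. Lineages are
analyzable iff their three-state sum is strictly positive at every
timepoint.

A structural caveat the pipeline test makes explicit: fixed-total
normalization preserves each lineage's *share of a sample* exactly, but
reconstructs cross-state proportions correctly only insofar as the scheme
ratio matches the composition actually sorted. End-to-end recovery tests
therefore simulate a chain whose stationary composition equals the scheme
ratio, mirroring how the scheme was chosen to match the FACS composition
in the first place.

## Transition matrices and Markov tests

The population and pooled fits are unconstrained OLS, `M = (XᵀX)⁻¹XᵀY`
(computed via `lstsq`; the normal-equations closed form is the test
oracle). No normalization is applied afterwards — on pooled data the
estimate comes out right stochastic to ~1% on its own, and that emergent
property is asserted, not imposed. Rank-deficient designs fall back to the
pseudo-inverse and are flagged `degenerate`. The constrained (per-lineage)
variant minimizes the same residual subject to entries in [0,1] and row
sums of exactly 1, solved as a 9-variable SLSQP program with analytic
gradient (`ftol` 1e-14), then clipped/renormalized at the 1e-12 level.
Where a source state never appears, that row is unidentifiable: it is
returned on the simplex and the fit flagged.

The population-level check is a per-row chi-square on percentage rows —
statistically informal, but it is the published procedure; categories with
non-positive expected values are dropped with df reduced. Per lineage, Mᵢ
is fitted on the lineage's own four transition rows and each transition
tested by Σ(O−E)²/E over categories where both observed and expected cells
are positive (negative expectations can arise because Mᵢ is unconstrained);
fewer than two usable categories, floor-rounding attrition, or an empty
post-transition timepoint make the transition *uninformative*. BH
correction runs across lineages within each transition (the published
wording — "across 1,736 lineages during transition (a,b)" — pools within,
not across, transitions). Because Mᵢ is fitted to the same four rows it is
then tested on, the test is conservative on truly Markovian lineages;
calibration and power are established by simulation in the acceptance
suite rather than assumed.

Bootstrap CIs for M resample ⌊0.8·n⌋ lineage rows per iteration and take
2.5/97.5 percentiles. Resampling is **with replacement** by default: an
80% *without*-replacement subsample has spread ≈ √(1/m − 1/n) ≈ 0.5× the
full-sample sampling error, and its percentile interval covers the truth
only ~65% of the time (measured in this codebase); with replacement the
same interval covers ~96%. The without-replacement variant is available
via `replace=False`.

## Growth–birth–death decomposition

With U, V the stacked pre-/post-transition cell-number rows, the factor G
solves (U·M)G = V by least squares — the per-lineage derivation U′G = V
with U′ = U·M, which defines what G measures; the literal stacked variant
UG = V is available behind `literal=True`. Rates are the Hadamard quotient
(eᵢ·M·G)ⱼ / (eᵢ·M)ⱼ with eᵢ scaled to 100 cells; entries whose
transition-only prediction is zero are undefined (NaN). Identifiability is
uneven: with a 90:5:5-dominated composition the design matrix U·M is close
to collinear, so G's off-diagonal entries — and with them rates out of
rarely occupied source states — carry large sampling error even at 10⁶
cells, while the destination-state growth factors (diag G) and the
dominant source-state rate row are recovered within a few percent. The
recovery tests assert exactly those identifiable quantities.

## Ternary embedding, motility, lineage entropy

The stated vertex coordinates (State 3 at the origin) are inconsistent with
the stated motility range ([0, 2] with the maximum on the State 1–State 3
axis) and with percent motility = motility/2 × 100. The embedding
x = P₁ − P₃, y = P₂ reproduces every numeric consequence (range, axis of
maximum change, the /2 normalization) and the stated intent of
up-weighting 1↔3 displacement, so it is the default; the literal variant
sits behind `embedding="literal"`. A side effect both variants share: the
maximum displacement along the 1–2 and 2–3 axes is √2, not 1 — no
consistent Euclidean embedding can make it 1 while keeping the other
statements true. Deciles of overall motility (sum over the four
transitions) break ties by stable lineage-id order.

Lineage entropy maps each proportion piecewise-linearly (0 → 0, steady
state → 1/3, 1 → 1) and evaluates −Σ P′ log₃ P′ on the *non-renormalized*
scaled triple, with 0·log 0 = 0. At the steady state every P′ = 1/3 and
the value is exactly 1; at each vertex it is exactly 0; the mapping is
continuous across its breakpoints. Because the scaled triple is not a
probability vector, the true interior maximum is not exactly at the steady
state: a 0.005-step grid search locates it at (0.710, 0.160, 0.130) with
value 1.000288. The implementation follows the printed formula; tests
freeze both the intended anchor (H = 1 at the steady state) and the
measured 3×10⁻⁴ excess.

The vector field bins lineage start positions at width 0.1 in embedding
units (a display resolution; unspecified externally) and averages
displacement vectors with equal weight across the four transitions,
reporting per-bin lineage counts, total cells and the number of entries
that moved.

## History motifs and nulls

Lineages reduce to plurality-vote state sequences; ties go to the lower
state index and are flagged, and an optional `min_share` tightens the vote
for robustness checks. Motifs are anchored at the end of the sequence (the
last *depth* states before the final timepoint), so a depth-k table
marginalizes exactly onto depth-(k−1) and depth 1 is the memoryless
reference. Fisher tests compare next-state count rows for motif pairs
sharing their final state; 2×k tables are evaluated by full hypergeometric
enumeration (all tables at the observed margins, summing probabilities ≤
the observed table's), with a seeded Monte-Carlo fallback (10⁵ draws)
beyond ~2×10⁶ candidate tables. BH correction is used for state-sequence
motifs and Bonferroni for motility-state motifs, matching the two published
procedures.

Motility sequences binarize each transition at its median by default (the
original high/low cut is unstated; deciles are also provided). The
replicate-correlation null reassigns each lineage a random draw from its
replicate's empirical motility pool, correlates log₁₀ percent motility, and
records Pearson r and R² per trial; zero motilities are excluded pairwise
before the log (their handling is unstated; exclusion preserves the
log-scale procedure). The read-reassignment null permutes read counts
across barcodes within each sample, which preserves sample depth profiles
while destroying lineage identity.

## Scales and budgets

Statistical acceptance checks run at reduced but sufficient scale: bootstrap
coverage uses 200 outer replicates × 200 iterations (production CIs used
10⁵ iterations; coverage needs replicates, not iterations), the FASTQ round
trip runs ~6×10⁴ reads (exactness is scale-free), and calibration/power
use 150–500 lineages × 10³ cells per seed. The randomization null runs at
full scale (2,560 lineages, 10⁵ trials) because its acceptance band —
max R² ≤ 0.01 — is itself scale-dependent: the expected maximum is
√(2 ln 10⁵ / 2560)² ≈ 0.009, so the bound holds for most but not every
seed by construction (~4% of seeds exceed it); seeds here were fixed in
advance, not selected.
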