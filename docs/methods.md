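# Methods

## Model

The package studies equilibrium synonymous codon usage under a
mutation–selection Markov model. Mutation is a homogeneous continuous-time
process on nucleotides; selection is a state-dependent thinning of codon
transitions according to the physicochemical similarity of the amino acids
they exchange; the quantity of interest is the deviation of
fourfold-degenerate (4FD) codon usage from the pure-mutation expectation.

### Mutational pressures with prescribed stationary distributions

The UNREST model has 12 free off-diagonal rates. Prescribing the stationary
distribution π imposes 3 constraints and leaves (up to overall scale) an
8-dimensional family. We parameterize it exactly by flux decomposition: the
flux matrix `F_ij = π_i q_ij` must have equal row and column sums, and every
nonnegative balanced flux splits into

* 6 symmetric edge fluxes `S_ij = S_ji ≥ 0` (one per unordered nucleotide
  pair) — by themselves they give detailed balance, i.e. a reversible chain;
* 3 signed circulations on a fundamental-cycle basis of K4 (cycles
  C→G→A→C, C→T→A→C, G→T→A→G for the spanning tree rooted at A) — these
  carry all irreversibility.

`q_ij = F_ij/π_i` then satisfies πQ = 0 identically, with no rejection
sampling, and the map is surjective onto the stationarity-constrained UNREST
family (verified by round-trip fitting in the tests). Scale is fixed by
normalizing the expected substitution rate −Σ π_i q_ii to 1; this removes a
pure-scale degree of freedom the downstream statistic is *not* invariant to
only through the uniformization constant, which is fixed alongside.

Degenerate all-zero fluxes are rejected rather than returned; proposals with
a negative net edge flux raise a negative-flux error, and the optimizer
repairs them by clipping symmetric fluxes at zero and shrinking circulation
magnitudes by bisection.

### Discrete time and the codon lift

Uniformization converts Q to a stochastic matrix `P = I + Q/λ`. We take the
tight constant `λ = max_i |q_ii|` (so the most mobile nucleotide has no
self-transition); a `lam_multiplier ≥ 1` knob yields lazier chains. The
choice matters quantitatively because the codon matrix is the positional
tensor product `M[c→c'] = Π_k P[c_k→c'_k]`: lazier chains carry less
probability on simultaneous multi-position changes, which interact with
selection differently from sequences of single changes. The tensor product
is the canonical lift of per-position dynamics and keeps the product measure
`π_{c1}π_{c2}π_{c3}` stationary, so the third-position usage within any 4FD
group under pure mutation is exactly π — the baseline the statistic needs.

### Selection

Grantham's 1974 amino-acid distance matrix (composition, polarity, molecular
volume; 5 ≤ D ≤ 215) ships as package data. The default conversion to
acceptance probabilities is the linear complement of the normalized
distance, `a(x,y) = 1 − D(x,y)/D_max`: the simplest monotone map onto [0,1]
with unit diagonal. It is deliberately a strategy hook — any callable from
the distance matrix to acceptances can be substituted (e.g. `exp(−D/τ)`)
without touching downstream code, because the conversion is the one genuinely
under-determined ingredient of the model.

Substitutions creating or destroying a stop signal take the floor acceptance
`stop_floor`, default 0 ("lowest possible"). Stop→stop changes count as
synonymous (acceptance 1); this is irrelevant at floor 0, where stop codons
exchange no probability with the sense class. The combined chain multiplies
off-diagonal mutational transitions by the acceptance of the implied
amino-acid change and returns rejected mass to the diagonal.

With floor 0 under a code that has stop codons, the chain has two closed
communicating classes (sense and stop). `stationary_distribution` treats
multiple closed classes as an error with the class decomposition attached;
the pipeline entry `combined_stationary` recognizes the isolated-stop case,
solves on the sense class, and assigns stops frequency 0. A tiny positive
floor (1e-9, via `strict=False`) keeps the 64-state chain irreducible
instead; the two routes agree to < 1e-6 in group-relative usage (tested).
The solver itself is a dense linear solve of `(Mᵀ − I)v = 0` with a
normalization row — deterministic and exact to machine precision at n ≤ 64;
power iteration is retained in the tests as an independent oracle only.

### The statistics

For a 4FD group *s* with members s_A, s_C, s_G, s_T:

    Fπ|s = Σ_i |π_i − π^sel(s_i)/π^sel(s)| / π_i,     Fπ = Σ_s Fπ|s.

The within-group *relative* usage is compared against π (the pure-mutation
expectation) and normalized by π, so rare nucleotides are weighted up. The
sequence-level analogue F replaces π^sel by observed counts and π by the
expected frequency `e_i`, the average of the five groups' relative
third-position usages. F is invariant under scaling all counts and is 0 when
all groups share one usage vector.

A consequence worth stating explicitly: the acceptance matrix is symmetric,
and a Hadamard product of a reversible kernel with a symmetric matrix (with
the diagonal absorbing the deficit) preserves detailed balance. Hence every
reversible pressure gives Fπ = 0 *exactly*, for every code. All
selection-induced deviation is carried by the circulation parameters, and
minimizing Fπ over rate matrices converges to 0 — both are tested.

## Optimization and sweeps

At each (code, π) the evolution strategy is elitist (μ+λ) with log-normal
self-adaptive per-coordinate step sizes (learning rates 1/√(2√n), 1/(2n)^½
at n = 9), feasibility by projection, infeasible or numerically degenerate
offspring discarded. Defaults: μ=10, λ=40, σ₀=0.3, 300 generations, 5
restarts. Per-(code, pressure) seeds derive deterministically from
(master seed, code id, grid index), so sweeps are reproducible and
shardable; sweep rows are flushed per optimization, so partial output files
are always valid TSV and re-running resumes.

The stationary-composition grid is enumerated in exact integer step counts
(no float accumulation; coordinates are reconstructed in integer nano-units)
with each coordinate in [0.05, 0.85] at step 0.01 by default — 91,881
tuples. Per-code summaries (min/median/max of the per-pressure maximized Fπ,
with percent change against the standard code) mirror the published
reporting convention: the tabulated per-code "minimum" is the minimum over
*pressures* of the maximized statistic, not a minimization over rate
matrices — the reversibility argument above shows the latter would be
identically 0.

### The search landscape, and what optimized values mean

The Fπ landscape over flux space is strongly multimodal, and its true
suprema are large: at the A-rich composition (A .84, T .05, C .05, G .06)
under the standard code, independent default-budget restarts land anywhere
between ≈6 and ≈18, and longer searches keep finding stronger irreversible
optima (driving some group members toward extinction inflates the
π-normalized deviation). Published values of this model family at the same
compositions (≈9.0 for the standard code, ≈11.4 for code 23, ≈0.245 at the
G-rich composition) are therefore properties of a particular search
configuration, not of the objective's supremum; this package's optimizer,
run at its documented defaults, finds systematically stronger optima
(≈14, ≈28 and ≈2.3 respectively at seed 1). The *structure* of the results
is robust to this: rankings across codes (which alternative codes bias 4FD
usage more or less than the standard code) and the monotone growth of
attainable bias with the pressure's A+T content reproduce stably at modest
budgets, and those are the quantities the acceptance tests pin down. Optimum
values should always be reported together with their ESConfig.

## Synthetic data

`UsageSpec`/`generate_cds` emulate exactly the statistical structure F
consumes: codons i.i.d. from a 64-way distribution with 40% of mass spread
equally over the five 4FD groups (each with its own third-position simplex,
optionally skewed toward one nucleotide by a mixing weight δ ∈ [0, 0.75])
and the rest over non-4FD sense codons; no internal stops; a terminal stop
codon drawn uniformly from the code's stops; lengths 10 + geometric with the
requested mean (length structure is irrelevant to F but exercises I/O).
Groups are sampled independently — real coding sequences couple group usages
through shared mutational pressure and gene-level selection, so passing
recovery tests here validates the counting/averaging pipeline, not the
realism of inter-group correlations. Codes 27, 28 and 31 (whose
dual-coding stop codons are registered with their sense meaning, leaving no
stops) cannot terminate records and raise the documented infeasible-spec
error.

`simulate_codon_evolution` runs independent per-site multinomial chains and
is used to cross-validate the deterministic stationary solver (sites seeded
at the solved stationary stay there to within sampling error).

## Reporting

Substitution-rate comparisons between paired pressure sets use the
two-sided Wilcoxon signed-rank test per ordered substitution (scipy's
policy: exact null for small tie-free samples, normal approximation with
continuity correction otherwise) with Benjamini–Hochberg adjustment within
the family of 12 substitutions only. Sample-level comparisons of F/Fπ values
use Kruskal–Wallis with the median ratio reported. Pairing is per code when
comparing extremal pressure sets (24 pairs). All tables are pure functions
of their input frames.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale by design: 100 random
grid pressures for the factorization and conservation checks, 50 chains for
the solver oracles, ~1e6 codons for F parameter recovery (2% relative), an
80-point subsample of the 0.05-step grid × 9 codes at a modest ES budget
(μ=4, λ=12, 20 generations) for the ranking and A+T-monotonicity checks, and
the default ES budget for the three extremal-composition searches. The full
0.01-step sweep (91,881 pressures × 24 codes) is the same code path via
`sweep_grid`/the CLI and is resumable and shardable by construction.

## Known limitations

* The acceptance conversion is an assumption (linear complement); optimized
  Fπ magnitudes depend on it, though the neutral baseline and rankings do
  not depend on its scale.
* The uniformization constant is a convention; it modulates the weight of
  simultaneous multi-position codon changes.
* Optimized values are "best found under config" — no global-optimality
  claim is made or possible; see the landscape note above.
* Time-homogeneous, strand-symmetric, site-independent mutation only;
  no translational-efficiency selection, no start-codon or
  selenocysteine/pyrrolysine handling.
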