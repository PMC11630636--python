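# Methods

## Model and assumptions

`permkin` treats ion permeation as a homogeneous Markov jump process over
discrete occupancy states of the selectivity filter. Two equivalent
parameterizations are used: a generator Q (off-diagonal rate constants in
s⁻¹, diagonal fixed by zero row sums) and the propagator T(Δt) = e^{QΔt} at
a lagtime Δt. All public interfaces take lagtimes in nanoseconds and convert
to seconds internally; the matrix exponential is scipy's scaling-and-squaring
Padé implementation, and the test suite checks it against a truncated Taylor
series on the bundled model. The stationary vector is obtained from the
eigen decomposition of Tᵀ. Because driven (voltage-biased) chains are
irreversible, the spectrum is generally complex: the eigenvalue closest to
1+0i is selected, the eigenvector must be real to within 1e-8 after phase
alignment, and a degenerate unit eigenvalue (reducible chain) is an error
rather than a silent multi-component answer.

## Charge flux

With n sites bounded by two bulk reservoirs there are n+1 intervals, and a
single ion move across one interval carries ±1/(n+1) of a permeation charge
(positive outward, i.e. intracellular → extracellular). States are first
projected onto ion-only configurations (`B` counts as ion, `W` as no ion):
water carries no charge, so states differing only in water placement
exchange zero flux. The base flux F_ij is the net charge along a pathway
with the fewest elementary moves, found by breadth-first search over
configurations with integer interval accounting (so every value is an exact
multiple of the quantum). Several shortest pathways can disagree in net
charge — they then differ by whole permeations; the implementation keeps the
smallest absolute flux, prefers the positive sign on an exact tie, flags the
pair as ambiguous, and logs it. Entry from the cavity into the innermost
site counts one interval; an outside ion reaching the second-outermost site
counts two (reservoir → outer site → inward hop).

The base F is exact only in the Δt → 0 limit. At a lagtime nΔt the
composite flux is built by the recursion

    F_ij(nΔt) = Σ_m T_im((n−1)Δt) T_mj(Δt) [F_im((n−1)Δt) + F_mj(Δt)] / T_ij(nΔt),

a pathway-probability-weighted average of the charge over all n-step routes.
Two variants share this code path: the *Markov* variant substitutes powers
of T(Δt) for the intermediate matrices, and the *empirical* variant uses
transition matrices observed at every multiple of the base lagtime. They
coincide exactly when the observed matrices are powers of the base matrix;
they diverge for lumped models, whose memory breaks the Chapman-Kolmogorov
relation. Entries with zero pathway probability get flux 0 and are flagged;
they cannot contribute to any current sum. Because the recursion is exact
given its base flux, the composite current at any nΔt reproduces the current
at the base lagtime — so the base must be chosen short enough that the
minimal-path approximation holds there (the pipeline uses the trajectory
frame interval; analytic checks on the bundled model use 0.01–0.1 ns, where
the discrete-time current matches the rate-form current to better than
0.1%).

## Currents

e₀ = 1.602176634e-19 C (exact SI); outputs are in pA. The boundary form
applies to single-cycle schemes; the rate-flux and transition-flux forms
work for arbitrary topologies; direct counting sums the base flux over
successive frames and divides by elapsed time, skipping window pairs that
span classification gaps. Multi-replica counting reports a duration-weighted
mean and a between-replica standard error. Estimators recompute the
stationary vector from the supplied T or Q unless the caller passes one
explicitly.

## Frame classification and counting

Sites are half-open axial intervals [lower, upper) along a z axis growing
from the intracellular to the extracellular side — half-openness makes
boundary assignment unambiguous, a choice the underlying geometric rules do
not themselves fix. Radial cutoffs default to 4 Å (8 Å for the wide
innermost site); the same cutoff is applied to water. The bundled default
boundaries are synthetic placeholders (real work derives them from protein
atoms upstream; that computation is deliberately outside the core, which is
format-agnostic and consumes per-particle (species, z, r) tables). The
innermost site admits only `K`/`W`: with neither particle present a cavity
water is assumed and `W` recorded with a debug log. Two ions in one site
are not representable in the alphabet and flag the frame; flagged frames
become gaps that break counting windows. Transition counting is sliding
(stride 1, overlapping windows) at any integer frame lag, accumulates
across replicas, and row-normalization drops states with no outgoing counts
(with their columns, logged). Empty-filter alphabets, gaps, and replica
accumulation are all exercised in the tests by hand-enumerated window
counts.

## Reduction

Lumping is implemented as one grouped-sum pass over an arbitrary partition:

    T^red_XY = Σ_{i∈X} P∞,i Σ_{j∈Y} T_ij / P^red_X,
    F^red_XY = Σ_{i∈X,j∈Y} P∞,i T_ij F_ij / Σ_{i∈X,j∈Y} P∞,i T_ij,
    P^red_X = Σ_{i∈X} P∞,i,

algebraically identical to repeated pairwise merging (verified to 1e-12 in
the tests) and free of order effects. The same F formula on X = Y captures
the charge exchanged between lumped partners on the diagonal, which is why
reduced flux matrices are a distinct kind (`reduced`) no longer constrained
to be antisymmetric. The construction preserves the stationary vector, all
in/out probability flows and charge flows, hence the current — exactly, at
the construction lagtime, for any partition of any ergodic chain (a
property-based test asserts this to 1e-9 pA on random chains and random
partitions). A macrostate with zero stationary mass is kept as a flagged
self-loop so the reduced matrix stays stochastic.

Macrostate counts are suggested by the largest ratio of consecutive
eigenvalue moduli (k ≥ 2); the suggestion is advisory and the clustering
CLI requires an explicit count. Fuzzy memberships come from the leading
Schur vectors (reordered by descending eigenvalue modulus; complex pairs
are never split — if the cut would split one, the operation fails loudly)
mapped onto the probability simplex by a greedy inner-simplex vertex search
and clipped barycentric coordinates. Schur vectors rather than eigenvectors
make the procedure well defined for irreversible chains. This is a
structural analogue of PCCA+-style clustering, not a reimplementation of
any specific published optimization; on exactly block-diagonal chains it
returns indicator memberships, and on constructed three-well metastable
chains every microstate's dominant membership exceeds 0.95.

## Rate-matrix fitting

Given a reduced T at a (Markovian) lagtime, the generator is recovered by
minimizing ‖T − e^{QΔt}‖_F over valid rate matrices, with off-diagonals
parameterized as exponentials of free variables (positivity by
construction, upper-bounded at 100/Δt since faster rates only saturate T),
initialized from the clipped real matrix logarithm of T, and restarted from
a few seeded perturbations (L-BFGS-B; deterministic given the seed). An
optional penalty λ·|I_T − I_Q| ties the fit to the current. The two
currents must be genuinely comparable estimates of the same quantity: I_T
is the discrete-time current of T with a flux matrix *at T's lagtime*
(e.g. the empirical composite), while I_Q is the rate-form current of the
candidate Q with the *short-lagtime* reduced flux. Conflating the two roles
lets the optimizer satisfy the penalty with physically meaningless
generators — an instability found during development and now excluded by
the interface. λ defaults to 0 in the library and CLI; the pipeline
defaults to λ = 1 (penalty in pA on the same scale as the typical Frobenius
residual) because its fits run at long lagtimes on estimated matrices,
where the unregularized problem is ill-conditioned: the propagator is
nearly flat there, so small statistical errors in T propagate strongly into
the rates. Fits on exactly known matrices recover the generating rates to
<1% and are insensitive to λ.

Large-lagtime fits carry a systematic residual for lumped models (the
reduced chain is not exactly Markovian at any lagtime): on the bundled
model's four-state reduction the fitted-rate current is ~2.01 pA at a 20 ns
fit against the true 2.09 pA, and the error shrinks monotonically as the
fit lagtime grows — the behavior the fitting procedure is designed to show.

## Synthetic data

The Gillespie simulator is the stand-in for MD: exponential holding times
with rate |Q_ii|, jump probabilities Q_ij/|Q_ii|, start state drawn from
stationarity by default (overridable, e.g. to reproduce relaxation
experiments), fully determined by one integer seed (replica r uses
seed + r). Discretization samples the event trajectory on a regular grid
with a left-continuous convention (a frame on a jump instant records the
new state) — MD frames have no such ambiguity, so the convention is
documented rather than configurable. What this emulates is the *kinetics*
of a permeation trajectory: exact Markovian dynamics, perfect
classification, no force-field error, no boundary recrossing artifacts, no
correlated noise. Passing tests on synthetic data therefore validate the
estimators and the algebra, not the classification geometry against real
MD output. Default study conditions mirror the worked example: the bundled
six-state model (exact current 2.0924 pA), 0.1 ns frames, a 1–30 ns lagtime
ladder, and eight replicas totalling 1 ms for the full-pipeline recovery
run (~1.7×10⁵ jump events); at that size the direct-count current has a
~1% standard error.

## Pipeline

The orchestrated protocol estimates T over the ladder; builds the base flux
at the shortest available lagtime — the frame interval — and compares its
current with the direct count (>10% relative mismatch warns that the
lagtime is too coarse); lumps per the configured strategy chain and
re-verifies the current; scans the ladder for the smallest lagtime whose
Chapman-Kolmogorov deviation against observed matrices at 2× and 3× that
lagtime stays below the advisory threshold (default 0.01 max elementwise;
the multiples may exceed the ladder top, since counting at any lag is
possible from the trajectories); builds the empirical composite flux there
and re-verifies; and finally fits the generator at that lagtime. If no
ladder lagtime passes, the pipeline halts after reduction with a diagnostic
report — on the bundled model's four-state reduction this genuinely happens
for ladders capped at a few ns, since that model only becomes nearly
Markovian around 20–30 ns. Runs are reproducible byte-for-byte from one
config seed.

## Known limitations

- The occupancy alphabet admits one ion per site; channels with genuinely
  multi-ion sites need a richer alphabet.
- Minimal-path ambiguity resolution (smallest |flux|, positive on ties) is
  a documented convention; alternative conventions would shift base fluxes
  by whole permeations on the affected (rare, ≥4-move) pairs.
- Rate constants are voltage- and concentration-independent; extrapolating
  beyond the simulated condition is out of scope.
- The composite-flux recursion inherits whatever error the base flux has at
  the base lagtime; it corrects lagtime dependence, not a bad base.
- Spectral clustering returns a structural PCCA+-analogue; it is validated
  on constructed metastable chains, not against any external clustering
  implementation.
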