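# Methods

## The model

dridscape treats a molecular-dynamics trajectory as a realization of a
Markov jump process over metastable conformational states and estimates
that process in four steps.

**Structural metric.** Each frame is mapped to a 3m-dimensional DRID
fingerprint: for each of m centroid atoms, the mean (mu), root-mean-square
deviation (nu) and signed-cube-root skew (xi) of the reciprocal distances
1/d to the reference atoms, in nm^-1. Atoms covalently bonded to a
centroid (and the centroid itself) are excluded from that centroid's sum,
and the denominator of every moment equals the number of terms actually
summed, making mu a true mean. The printed form of the normalization
(N - 1 - nb_i) can double-count when bonded atoms are also excluded from
the reference set; we resolve the ambiguity in favour of the exact count,
which coincides with the original DRID construction. xi uses the signed
cube root of the (possibly negative) third central moment, so skewness
direction is retained. The frame-to-frame dissimilarity is the blocked
metric s = (1/3m) * sum_i of per-centroid Euclidean norms — a positively
scaled sum of metrics, hence itself a metric; note it differs from the
plain Euclidean norm over the 3m-vector whenever m > 1, and assignment
uses exactly this blocked form.

Reciprocal distances weight local packing heavily: a positional
perturbation delta maps to a fingerprint perturbation of order
delta / d^2, so the closest non-excluded contacts dominate the noise
response. This matters for synthetic-data design (below).

**State decomposition.** Regular-space clustering in DRID space: one
sequential pass in frame order; frame 0 seeds the first center; a frame
becomes a new center iff its DRID distance to every existing center
exceeds the cutoff. Multiple trajectories are concatenated in input order
before seeding. Exceeding the center cap (default 2000) is a hard error
rather than a truncation, because clustering with a truncated center set
silently changes the entropy of the state decomposition; the remedy is a
larger cutoff. Assignment is nearest-center under the blocked metric with
ties broken toward the lowest center index. The implementation processes
frames in chunks but reproduces the strictly sequential rule exactly:
frames within the cutoff of an existing center can never seed, and
candidates are re-filtered against each newly accepted center in order.

**Kinetic network.** With occupation counts n_j and one-frame transition
counts C_jk (never counted across a trajectory boundary), the network
carries F_i = -ln(n_i/N) in k_B T (global minimum shifted to zero),
maximum-likelihood escape rates k_jk = C_jk/(n_j * dt) in ps^-1, and
symmetrized barriers: the reactant-anchored one-sided value
F_j - ln k_jk + ln(k_B T/h * 1 ps), averaged over the two directions.
The average is invariant to whether the one-sided formula anchors on the
reactant or the product, because both minima energies enter once either
way; only the average is reported. The prefactor ln(k_B T/h * 1 ps)
(~1.8655 at 310 K) is recomputed from CODATA constants, never hard-coded.
Pairs observed in only one direction get the missing rate completed by
detailed balance (k_kj = k_jk p_j/p_k) and are flagged in
`completed_pairs`; `strict=True` drops them instead. Barriers that fall
below an adjacent minimum — possible under finite sampling — are kept as
computed and recorded in `suspect_barriers`; only the disconnectivity
merging logic raises them to max(F_j, F_k) + epsilon, with a log message.
The network is restricted to the largest connected component of the
observed-transition graph; excluded minima are reported.

**Rate-estimator choice.** Observed one-frame transition frequencies
normalized by occupation time are the maximum-likelihood escape-rate
estimator for a jump process observed at fixed intervals in the
well-separated-timescale regime (jump probability per frame << 1). The
estimator lives in one function (`estimate_rates`) so alternatives can be
swapped.

## Disconnectivity graphs

Superbasins at descending thresholds FIRST, FIRST - DELTA, ... (LEVELS
values): minima j,k share a basin at threshold E iff a path of barriers
all strictly below E connects them ("below the threshold" is read as
strict; a barrier exactly at a threshold merges one level up). A minimum
first appears at the lowest threshold strictly above its own F_i. The
union-find construction is validated against brute-force all-pairs path
search in the tests. Layout: within each basin the branch holding the
lowest minimum is centered and the remaining branches alternate outward
in order of their lowest energies; ties break by minimum id, making the
layout deterministic. Rendering is native (matplotlib; SVG or PostScript)
with horizontal connectors at merge thresholds and vertical leaves ending
at F_i; `min.data`/`ts.data` remain dialect-compatible with
disconnectionDPS, so either renderer can be used on the same files. The
dinfo keywords DELTA / FIRST / LEVELS / MINIMA / TS are compatible;
LABEL_LOWEST, ORDER_PARAM, OUTPUT and FORMAT are this package's
extensions (the upstream tool's corresponding option names are not fixed
by any text source we treat as authoritative, so we document our own).
Color-map endpoints default to the order-parameter min/max. SVG output
fixes the hash salt and omits the date so reruns are bit-identical.

## First-passage-time kinetics

For product set A and reactant set B, the operator M over the surviving
states I u B carries k(b -> a) off-diagonal and minus the total escape
rate (including flux into A) on the diagonal. Reachability of A from
every surviving state is checked up front (stranded states are named in
the error). When the surviving-state fluxes satisfy detailed balance
(checked numerically at relative tolerance 1e-8), -M is symmetrized by
the sqrt-equilibrium-weight similarity transform and solved with a
symmetric eigensolver, guaranteeing real eigenvalues; otherwise a general
dense solver runs with per-eigenpair residual checks (1e-9) and an error
for near-defective systems. Amplitudes come from the spectral expansion
of the survival function S(t) = sum_alpha P_alpha(t); total absorption
implies sum_l A_l = 1, which the tests assert to 1e-8.

**Initial condition.** Set-to-set transitions start from local
equilibrium within B (p proportional to equilibrium weights restricted to
B). This is a documented package choice — the upstream convention is not
fixed — and a flag allows uniform-on-B or a single start state; the
per-state WAITPDFPRINT outputs use the single-state start. The
log-time density P(y) = sum_l nu_l exp(y - nu_l e^y) A_l is written on a
grid spanning [-ln nu_max - 10, -ln nu_min + 10] (2001 points): the left
tail decays like e^y, so a margin of w leaves e^(-w) unaccounted mass —
10 suffices for 1e-4 normalization of the written files; the tests use
wider grids where they check to 1e-6. Peaks are located on a dense grid
and refined by bisection on dP/dy. Times are ps throughout, so the first
column of every waitlnpdf file exponentiates to ps.

Reading `min.data`/`ts.data` back reconstructs directed rates by
inverting the Eyring relation, k_jk = (k_B T/h * 1 ps) exp(-(F_hat -
F_j)) — the exact inverse of how barriers were computed whenever the
underlying rates satisfied detailed balance, and the natural (detailed-
balance-consistent) completion otherwise. Energies are written with %.17g,
which round-trips IEEE doubles exactly; the vibrational/symmetry/inertia
columns of the dialect are written as neutral constants (1.0 / 1 / 1.0)
because free-energy networks do not use them, and downstream tools parse
them cleanly.

## Synthetic data: what it emulates and what it does not

The generator plants a landscape (chain, funnel, or two-funnel topology),
samples minima energies uniformly on [0, 2.5] k_B T — the scale of the
state splittings reported for small disordered peptides — and barriers
6.5–8 k_B T above the higher adjacent minimum (the funnel-joining barrier
of the two-funnel topology is raised 1–2 k_B T above every intra-funnel
barrier). Rates follow the same Eyring inversion the estimator assumes,
so detailed balance holds by construction and recovered quantities can be
compared to planted ones without estimator bias. State trajectories are
sampled in discrete time with per-frame jump probabilities k*dt at a
default saving interval of 20 ps (the standard interval for this kind of
analysis); the barrier floor keeps every per-frame total jump probability
below 0.5, the validity bound of the first-order discretization, which
the sampler enforces. Dwell times are drawn geometrically, which is
exactly equivalent to per-frame Bernoulli jumps. The FPT module's
cross-check sampler is, deliberately, continuous-time kinetic Monte
Carlo — the discrete emitter mimics fixed-interval MD saving, the
continuous oracle mimics the master equation itself.

Toy coordinates are random self-avoiding bead chains (bond 0.38 nm, the
Cα–Cα spacing) with isotropic Gaussian jitter of 0.002 nm. The jitter is
deliberately small: through the 1/d^2 noise amplification above, 0.002 nm
of positional noise already produces ~0.01 nm^-1 of DRID spread.
Generation retries until the smallest inter-template DRID distance
exceeds 8x the empirically measured jitter spread and records both scales
on the template; `suggested_cutoff` (4x the spread) then sits safely
between the within-state and between-state scales even for the extreme
frames of a 10^6-frame trajectory. Trajectories are written as PDB (with
CONECT records, so bond-based exclusions need no guessing) plus XTC;
XTC's 0.001 nm coordinate rounding is below the jitter.

What passing tests on this synthetic data do **not** show: robustness to
trajectory non-Markovianity, to overlapping state basins (real IDP
ensembles are not well-separated Gaussians in DRID space), to cutoffs
mis-matched to the landscape, or to force-field realism. The generator
validates the estimators and the plumbing, not the science of any
particular system.

## Numerical and interface choices

- Units fixed package-wide: nm, nm^-1, ps, k_B T (coordinates arriving in
  Angstrom from MDAnalysis are converted on read). This matches the
  conventional 0.02 nm^-1 cutoff and 20 ps saving interval.
- Selections use the MDAnalysis selection language directly (the
  convention in this analysis ecosystem) rather than a bespoke grammar;
  bond exclusions come from topology connectivity, from distance-based
  guessing when the topology has none, or from an explicit bond table.
- Whether centroid atoms other than the one being evaluated belong to the
  reference set: only the evaluated centroid and its bonded atoms are
  excluded, per the exclusion rule as stated; other centroids remain
  ordinary reference atoms if the selection includes them.
- Zero centroid–reference distance is a hard error (the reciprocal
  diverges), reported with the frame index.
- Cluster models serialize to self-describing versioned JSON rather than
  a pickled object, for cross-language reproducibility; a version
  mismatch is an explicit error.
- State ids are 0-based internally and 1-based only in the PATHSAMPLE-
  dialect files (min.data ordering, ts.data references, min.A/min.B,
  order-parameter line numbers, waitlnpdfX.ID suffixes).
- The pipeline caches stages by SHA-256 of input files plus the consumed
  configuration keys; a stage reruns when its inputs changed or its
  recorded outputs are missing/corrupted. Deterministic stages plus fixed
  seeds make fresh artifact directories bit-identical.

## Problem sizes

The test suite and the acceptance script size their studies as follows:
oracle checks use 100 random 50-atom frames (moments) and 1000 random
triples (metric axioms); clustering contracts are asserted on 1e5 frames;
superbasin construction is cross-checked on 200 random networks of up to
12 minima; spectral-vs-ODE agreement on 50 networks of up to 10 states;
the stochastic cross-check uses 20,000 kinetic Monte Carlo first-passage
samples on a 5-state network; and the end-to-end recovery study uses a
6-state two-funnel landscape sampled for 1e6 frames at 20 ps. These sizes
give comfortable statistical resolution for every asserted tolerance
(e.g. ~0.2% relative standard error on the KMC mean, population errors
resolved at the 1e-3 level).

## Known limitations

- No maximum-likelihood MSM estimation with detailed-balance constraints,
  no lag-time/implied-timescale validation, no Bayesian error bars: rates
  are the plain observed-frequency estimator.
- The general (non-detailed-balance) eigensolver path rejects complex
  spectra rather than handling oscillatory modes.
- No trajectory alignment or periodic-boundary imaging: molecules are
  assumed whole; no alternative featurizations (contacts, dihedrals).
- The disconnectivity renderer covers the analysis outputs used here, not
  the full option surface of the upstream drawing tool.
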