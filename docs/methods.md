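# Methods

This note documents the models, estimators and numerical choices behind
`counterstream`, in the spirit of a package's statistical reference
manual. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Graph representation

Connectomes are area-labelled directed graphs without self-loops. Binary
networks store a boolean adjacency matrix; weighted connectomes store
three per-edge attributes — FLN (fraction of labelled neurons, the
tract-tracing connection weight, strictly positive and normalised over
sources per injected target area), SLN (fraction of supragranular
labelled neurons, in [0, 1]) and projection distance in mm — sharing one
structural edge mask. An absent edge is a masked entry, never a
zero-valued weight: FLN = 0 in an input matrix means "no edge". Node
order is the file's row order; supplementary-style files do not state
whether rows are sources or targets, so every loader takes an explicit
`orientation` flag.

## Paths, edge betweenness and convergence degree

Binary mode enumerates **all** minimum-hop paths per ordered pair from
the BFS predecessor DAG. Weighted mode assigns each edge the traversal
cost `(dist/FLN)^alpha` — distance raises the cost, anatomical strength
lowers it; `alpha = 0` collapses to hop counting, `alpha = 1` is plain
cost minimisation — and retains the `k` cheapest loopless paths per pair
(Yen's algorithm via networkx `shortest_simple_paths`). Retaining several
near-optimal paths restores the tie structure that makes convergence
degree informative on real-valued costs, where exact cost ties are
measure-zero. Cost comparisons treat values within a relative 1e-9 as
tied, and ties at the k-th rank are broken by lexicographic node-sequence
order so that output is deterministic.

Edge betweenness on a retained set generalises the classic count: each
ordered pair contributes, per edge, the fraction of its retained paths
through that edge. This implies the conservation identity
`mean EB = ASP * (#reachable ordered pairs) / m`, which the tests use to
cross-check the path machinery against the scalar metrics. CD uses the
In/Out origin/terminus sets of the retained paths; an edge traversed by
no retained path beyond (possibly) its own one-edge path gets
`In = {i}`, `Out = {j}`, CD = 0.

Two counting conventions exist for "unused" edges in the alpha
optimisation; the default counts edges whose EB comes only from their own
pair's direct path (the trivial one-edge path excluded), with a flag for
plain `EB == 0`. The alpha selector returns the **largest** grid value on
the joint-minimum plateau of unused-edge count (absolute tolerance 0,
i.e. exact integer agreement with the grid minimum) and maximum EB
(relative tolerance 0.05) — keeping the influence of the empirical
weights as high as the two criteria allow. The k selector min-max
normalises Fisher excess kurtosis of the EB distribution and the zero-CD
count over the grid and takes the k minimising their sum (smallest k on
ties); a degenerate constant EB distribution contributes kurtosis 0.
Because edge costs do not depend on k, the k-grid is evaluated by
computing paths once at the largest k and truncating.

A note on degenerate parameters: the relaxed structure at `alpha = 0,
k = 1` reproduces binary hop *distances* but not the binary *path set* —
binary mode keeps all tied minimum-hop paths, the relaxed scheme keeps at
most k (and beyond the ties, longer detours). The two CD structures
coincide exactly only on graphs with unique shortest paths.

## Scalar metrics and the Laplacian convention

ASP averages shortest-path lengths over reachable ordered pairs only (the
all-pairs denominator is recovered when the graph is strongly connected);
once removals disconnect the graph this reading keeps the quantity
finite and interpretable. The diameter of a disconnected digraph is the
largest diameter over its strongly connected components. Transitivity is
the global triangles-to-triples ratio of the undirected projection;
reciprocity is the fraction of directed edges whose reverse exists.

Synchronizability metrics come from the graph Laplacian. The default is
the **directed** Laplacian `L = D_out − A`: it has zero row sums (so 0 is
always an eigenvalue with the uniform eigenvector) and, by Gershgorin,
eigenvalues with non-negative real part; the spectrum is reported as
sorted real parts. This convention was selected empirically: on matched
directed Erdős–Rényi ensembles (n = 44, m = 630, 30 instances) it
reproduces the reference ensemble statistics (λ₂ ≈ 8.2, λ_max ≈ 21.5,
eigenratio ≈ 0.38) where the symmetrised `W = (A + Aᵀ)/2` convention
lands noticeably higher on λ₂ (≈ 9.0) and the union convention far off
(≈ 15.6). The symmetrised convention remains available
(`convention="mean"`) and is the one with a clean interlacing guarantee:
removing an edge subtracts a PSD rank-one term, so every eigenvalue —
λ₂ in particular — is non-increasing along any removal trajectory. The
directed spectrum does not share that guarantee, which is why the
monotonicity tests run under the symmetric convention. Eigenvalues below
1e-8 in magnitude are clamped to zero before ratios are formed.

## Edge-removal experiments

Strategies rank edges by recomputed criteria after every deletion
(descending EB; descending CD; ascending CD; descending |CD|; uniform
random). Ties are broken lexicographically by (source, target) labels —
the choice is arbitrary but makes trajectories reproducible.
`recompute=False` ranks once and deletes in that fixed order, as a
regression guard for the recompute semantics. Controls: directed G(n, m)
ensembles matched on node and edge count, and degree-preserving
randomisations by directed double-edge swaps (10·m attempted swaps;
swaps creating loops or duplicates are rejected), 30 instances by
default. Trajectory ensembles report per-step mean ± sd. Moving-average
smoothing of diameter curves is a plotting concern and not part of the
stored trajectories.

## SLN hierarchy model

Levels maximise the beta-binomial likelihood of per-edge supragranular
counts with mean `linkinv(h_target − h_source)` (logit link by default;
probit behind a flag — the two give rank-identical hierarchies on
synthetic data) and a common precision ν. Only level *differences* are
identified, so a reference area — by default the area with the lowest
incoming-SLN sum, i.e. the bottom of the hierarchy — is pinned at 0.
When true neuron counts are absent, per-edge pseudo-counts
`n_ij = max(1, round(cse · FLN_ij · n_areas))` weight the edges
(`cse = 1000` by default); FLN is the natural proxy for the number of
labelled neurons behind each SLN fraction, and the `n_areas` factor makes
an average-weight edge carry about `cse` trials after the per-target FLN
normalisation. Optimisation is L-BFGS-B with three starts (one
moment-based, two jittered), tolerance 1e-8 on the log-likelihood, and
`log ν` bounded to [−10, 12] — beyond `ν ≈ e¹²` the beta-binomial is
numerically binomial and the likelihood flat, which otherwise stalls the
optimizer. A weakly disconnected SLN graph raises an identifiability
error. SHD sums absolute pairwise level differences over unordered pairs
(signed sums would cancel).

## Laminar dynamics

Each area holds four rate populations (supra E/I, infra E/I) obeying
`τ_p dr_p/dt = −r_p + f(I_p)` with `f(x) = x/(1 − e^{−x})`, integrated by
Euler–Maruyama with additive noise `σ_p √(2 dt/τ_p) η_t`. Time constants
(6/15 ms supragranular, 30/75 ms infragranular), the local E–I coupling
matrix and the interlaminar pathways (supra E → infra E, infra E → supra
I) are inherited from the published reference implementation of the
bilaminar cortical model and live in the versioned
`laminar_defaults.json`; the simulator refuses to run if an entry is
missing. The background drive (16/6/14/6) is this package's choice: it
sets the operating point so that the linearised supragranular resonance
sits near 47 Hz and the infragranular one near 10 Hz, comfortably inside
the 30–70 Hz and 6–18 Hz analysis bands (the resonances are damped, with
Q ≈ 1.7, so a low operating point lets the peaks drift out of band).

Inter-areal coupling on edge i→j scales with `g(FLN) = G·FLN^0.3`
(the compressive exponent inherited from the reference model); the
feedforward component (weight ∝ SLN) runs supra-E → supra-E, the feedback
component (∝ 1−SLN) originates in infra E and contacts all four target
populations with fixed coefficients (0.1, 0.5, 0.9, 0.5). Delays are
`dist/velocity` (3.5 mm/ms) rounded to integration steps with a floor of
one step; rates are buffered in a ring of past states. Noise streams are
seeded per area from the run seed and a CRC of the area label, so a
subnetwork simulation reproduces the full network's per-area streams —
this is what makes the decoupling property (zero inter-areal gain ⇒
every area equals its isolated simulation) exact rather than merely
statistical.

## Spectral Granger causality

The estimator is nonparametric: DPSS multitaper cross-spectra (segments
of `segment_s` seconds, half-bandwidth `bandwidth_hz`, non-overlapping,
averaged over tapers and segments), factorized by Wilson's algorithm into
a minimum-phase transfer function H and innovation covariance Σ with
`S = H Σ H†`. The iteration's causal projection halves and
upper-triangularises the zero-lag coefficient; convergence is declared at
a relative update below 1e-8 or — because the finite frequency grid
imposes a floor on the achievable update — at a plateau, accepted only if
the plateaued update is already below 1e-2. Conditional GC from s to t
given the rest uses the two-factorization partition: the reduced system
(all series except s) is factorized separately, its transfer embedded
with an identity row for s and inverted against the full transfer
(`Q = Ḡ⁻¹H`), and the Geweke log-ratio taken on the transformed system
with the source's innovation variance partialled on the remaining
channels. With exactly two series the classic unconditional bivariate
measure is used. A parametric route (`var_spectral_matrix`,
`var_spectral_gc`) computes exact spectra and spectral GC of a known VAR
for cross-checks; the tests verify the estimator against that closed
form, against the Geweke frequency-integral identity, and against the
defining property of conditioning (suppression of the mediated link in a
chain).

DAI is the normalised GC asymmetry per frequency; frequencies where both
directional GCs vanish get DAI 0 and are flagged. Band DAI is implemented
as the band *average* (integral divided by bandwidth) so it stays in
[−1, 1]; the unnormalised integral differs by a per-band constant and
cannot affect any correlation. The multifrequency index is
`mDAI(i→j) = (DAI_γ(i→j) − DAI_α(i→j))/2` — gamma plus sign-inverted
alpha in the *same* direction, the only convention consistent with the
stated rationale of inverting the alpha/beta band because of its negative
correlation with SLN (the printed index pattern with the opposite alpha
direction contradicts that rationale and is not used).

**Recording proxy.** GC between areas is computed by default on an
LFP-like laminar mixture, 0.3·supraE + 0.7·infraE (deep layers dominate
field potentials). A supragranular-only recording is selectable but
cannot exhibit feedback alpha-band causality even in principle: the
source area's alpha rhythm is generated in its infragranular circuit and
is largely absent from (and unpredictable by) its own supragranular
trace, so the estimator attributes the feedback influence to noise. With
the mixed proxy the expected counterstream signature appears on strongly
hierarchical synthetic networks — SLN correlates positively with DAI in
the gamma band and negatively in the alpha band — which the test suite
asserts. Rates are decimated (anti-aliased) to ~250 Hz before spectral
estimation; the analysis bands end at 70 Hz.

## Synthetic connectomes

Areas are embedded uniformly in a 2-D box (default 40 mm); edge i→j is
placed with probability proportional to `exp(−λ·d_ij)` (λ = 0.08/mm), a
global scale solved by root-finding so the expected density — including
reciprocal completion with probability `reciprocity_bias` — hits the
target; defaults (29 areas, density 0.64, reciprocity 0.7) mimic the
dense macaque inter-areal graph. FLN is log-normal (log-mean −4, log-sd
2, spanning several orders of magnitude) normalised over sources per
target; SLN is beta-binomial around `logistic(slope·(h_j − h_i))` with
latent levels spread over two logit units. `bb_dispersion = 0` is the
noiseless limit (SLN equals its expectation exactly, counts stored as
expected splits). The generator reproduces the statistical *assumptions*
of the analysis — per-injection weight normalisation, laminar-fraction
hierarchy, distance-dependent connectivity — but not every empirical
regularity of real cortex: in particular the placement and weights are
independent of the latent hierarchy, so topology-derived indices (CD)
carry no built-in correlation with SLN. Passing tests therefore
demonstrate estimator correctness and the SLN-mediated coupling between
anatomy and simulated dynamics, not an anatomical claim about real
connectomes.

## Problem sizes and scaled-down experiments

Default test/experiment sizes are chosen so the full analysis chain stays
desk-scale: 30-instance control ensembles; 16–29-area synthetic
connectomes; 5–9 s simulations for spectral estimates; and the
subgraph-dynamics experiment at 20 random 8-area samples (the
full-scale version uses 200 dynamical samples and 10,000 topological
ones). At 20 samples the per-sample correlation estimates are noisy, so
the association between the invCDw×SLN and invCDw×mDAI correlations is
asserted by a pairwise-concordance sign test rather than a threshold on
the correlation of correlations.

## Known limitations

- The empirical 44-area and 29-area supplementary connectomes are not
  redistributed; the two acceptance tests tied to their published values
  fail (with an explanatory message) unless the files are supplied under
  `data/empirical/`.
- The directed-Laplacian spectrum is reported via real parts; for graphs
  far less reciprocal than cortex the imaginary parts grow and λ₂ loses
  its clean algebraic-connectivity reading (use `convention="mean"`).
- The laminar model omits dual-counterstream within-layer pathways and
  any spiking detail; its parameters are tuned for band placement, not
  for fitting physiological rate magnitudes.
- Wilson factorization assumes a positive-definite spectral matrix;
  supply enough tapers × segments relative to the channel count, or the
  iteration stalls above its acceptance floor and raises.
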