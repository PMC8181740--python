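# counterstream

Analysis of how convergence/divergence topology shapes resilience,
synchronizability and hierarchical oscillatory dynamics in directed
cortical networks — for computational neuroscientists working with
tract-tracing connectomes (binary directed area graphs, or weighted graphs
carrying FLN connection weights, SLN laminar-origin fractions and
projection distances).

## What it computes

**Convergence degree.** For a directed edge `(i, j)`, collect every
retained shortest path that traverses it; let `In` be the set of path
origins and `Out` the set of path termini. Then

    CD(i, j) = (|In| − |Out|) / |In ∪ Out|  ∈ [−1, 1],

positive for convergent (funnel-like, feedback-flavoured) edges and
negative for divergent (broadcast-like, feedforward-flavoured) edges. On
binary graphs the retained set is all minimum-hop paths. On weighted
connectomes a *relaxed* scheme is used: the edge traversal cost is
`(dist/FLN)^α` — α trades the influence of the weights against the number
of hops — and the `k` cheapest loopless paths per ordered pair are
retained (Yen's algorithm). α is chosen by jointly minimising the number
of unused edges and the maximal edge betweenness, `k` by jointly
minimising the EB-distribution kurtosis and the number of zero-CD edges.
Node reductions (`nrCD`, CD-flow Φ) turn edge CDs into a topological
hierarchy of areas.

**Resilience.** Targeted edge removal (by EB, maxCD, minCD, absCD, or at
random, recomputing the criterion after every deletion) with per-step
trajectories of transitivity, strong connectedness, average shortest path,
diameter, and graph-Laplacian spectral measures (algebraic connectivity
λ₂, spectral radius, eigenratio λ₂/λ_N), compared against Erdős–Rényi and
degree-preserving rewired control ensembles.

**Anatomical hierarchy.** Beta-binomial GLM with a logit link fitted to
supragranular counts: `E[SLN(i→j)] = logistic(h_j − h_i)`, giving area
levels `h` (reference pinned at 0), pairwise hierarchical distances and
their sum (SHD).

**Laminar dynamics and causality.** A bilaminar Wilson–Cowan model per
area (gamma-resonant supragranular and alpha/beta-resonant infragranular
E–I pairs), coupled across areas by SLN-split feedforward/feedback
projections weighted by `FLN^0.3` with distance delays. From the simulated
rates, conditional spectral Granger causality (multitaper estimation +
Wilson spectral factorization, Wen-style partition), the directed
influence asymmetry index `DAI(f) = (GC_{s→t} − GC_{t→s})/(GC_{s→t} +
GC_{t→s})`, its band averages (alpha 6–18 Hz, gamma 30–70 Hz) and the
scalar `mDAI = (DAI_γ − DAI_α)/2`.

A synthetic-connectome generator (exponential-distance-rule placement,
per-target log-normal FLN, beta-binomial SLN from a latent hierarchy)
makes every stage testable without tracing data.

## Worked example

```python
import numpy as np
import counterstream as cs

# a macaque-like synthetic 29-area weighted connectome + true hierarchy
net, levels = cs.generate(cs.SyntheticSpec(seed=11))

# relaxed weighted paths -> edge betweenness and convergence degree
em = cs.edge_metrics(cs.relaxed_weighted_paths(net, alpha=0.07, k=8), net)
print(em.table[["source", "target", "eb", "cd"]].head(3))

# SLN-based hierarchy recovers the generator's latent levels
fit = cs.fit_hierarchy(net)
true = np.array([levels[a] for a in net.nodes])
print("level recovery r =", np.corrcoef(true, fit.level_array(net.nodes))[0, 1])
```

prints

```
  source target   eb      cd
0    A00    A01  2.0  0.0625
1    A00    A02  4.0  0.5000
2    A00    A05  5.5  0.0000
```

(per-edge betweenness and convergence degree; A00→A02 is a convergent
edge, A00→A05 a balanced one) and

```
level recovery r = 0.9970340763029333
```

— the fitted anatomical hierarchy is essentially the generating one.

There is also a CLI: `counterstream synth|paths|cd|optimize|metrics|
attack|hierarchy|simulate|gc|sample|run ...` (see `--help`).

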