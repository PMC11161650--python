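# Methods

This note records the model, the numerical choices, and the design
decisions behind `endonet`, in the spirit of a statsmodels-style model
document: what is computed, under which assumptions, and what the tests do
and do not establish.

## Dynamics

Each agent `x_i` of the signed network evolves by Hill production minus
first-order decay,

    dx_i/dt = g_i(x) − η_i x_i,
    g_i(x) = [A_i/(1+A_i)] · [1/(1+B_i)],
    A_i = Σ_{u∈U_i} a x_u^n,   B_i = Σ_{v∈V_i} a x_v^n,

with activator set `U_i` and inhibitor set `V_i` read off the edge table.
All quantities are dimensionless; time is measured in units of the decay
time at `η = 1`.  Defaults `n = 3`, `a = 10`.  Consequences worth keeping
in mind:

- `g_i ∈ [0, 1)`; `g_i` is nondecreasing in every activator and
  nonincreasing in every inhibitor.
- There is no basal production term.  A node without activators is pinned
  at zero, and the all-off state `x = 0` is a fixed point of **every**
  network, with Jacobian `−diag(η)` — always locally stable.  Motif
  intuitions carried over from models with basal production (e.g. "the
  toggle switch has exactly two attractors") must be adjusted: the
  mutual-inhibition/self-activation toggle here has the two polarized
  states *and* the all-off state, with the saddles on the coordinate axes.
  On the toggle's diagonal the doubly saturated production
  `A/(1+A)²` stays below the diagonal, so symmetric trajectories decay to
  the origin rather than crossing a diagonal saddle.

### The degradation layer

Degradation rates `η_i = 1/τ_i` are dynamic:

    dη_i/dt = κ [ (dx_i/dt)² + 2 (dx_i/dt) η_i x_i ],   κ = 3/2.

Algebraically this equals `κ [g_i² − (η_i x_i)²]`, which exposes the
mechanism: η_i relaxes toward `g_i/x_i`, the value at which production and
decay balance, and freezes exactly when `dx_i/dt = 0`.  Three consequences
shape everything downstream:

- **Fixed points form manifolds.**  Any `(x*, η*)` with `g(x*) = η* x*`
  is a joint fixed point; where a trajectory lands on the manifold depends
  on its initial `(x, η)`.  Sampling many random initial conditions
  therefore yields many *unique* expression profiles (hundreds at the
  55-node scale) rather than a handful of isolated points — this is the
  intended source of within-domain heterogeneity, and it is why landscape
  analysis clusters profiles into domains instead of counting points.
- **The layer suppresses oscillations.**  Averaged over a cycle,
  `⟨dη/dt⟩ ≈ κ⟨(dx/dt)²⟩ > 0`, so η climbs until the oscillation damps
  out.  Sustained limit cycles therefore require the fixed-degradation
  mode (below); in the default mode oscillatory transients appear as
  `oscillatory`-classified trajectories at the integration horizon.
- **η can transiently go negative.**  During downward transients
  `dη/dt < 0` is possible and nothing in the law bounds η away from zero.
  Negative degradation is unphysical and destabilizes integration, so η is
  floored at `eta_floor = 1e-3` (clipped, logged).  Clipping events are
  rare in practice and confined to fast transients.

Setting `eta_dynamics=False` freezes `η` at `eta_fixed` (default 1) and
recovers the classical fixed-degradation endogenous-network form; all
oracle-equivalence tests run in this mode because isolated fixed points —
not manifolds — are what a grid oracle enumerates.

### Clamps

An intervention holds nodes at fixed values (0/1 by default, any value in
[0, 1] via `ClampSet(binary_only=False)`).  Both `dx/dt` and `dη/dt` of a
clamped node are exactly zero — the clamp overrides the node's own
degradation bookkeeping, which the law leaves unspecified; freezing is the
conservative choice.

## Integration and steady-state detection

Trajectories are integrated with LSODA (adaptive, stiffness-switching)
with an analytic Jacobian of the joint `(x, η)` system; Hill systems at
`n = 3` are moderately stiff near switching thresholds.  Tolerances
`rtol = 1e-8`, `atol = 1e-10`; horizon `t_max = 500`; convergence requires
the free-node residual `max_i |dx_i/dt|` to stay below
`steady_tol = 1e-8` across a trailing window of 10 time units.  A
nearly-converged state (residual < 1e-5) is Newton-polished onto the
exact fixed point at frozen η — the polished point is a genuine fixed
point of the joint system because `dη/dt` vanishes with `dx/dt`; the
polish is accepted only when the step is small (< 0.05) and the residual
drops below `steady_tol`, which both accelerates termination and sharpens
deduplication.  A bounded non-converged trajectory whose trailing
per-node amplitude exceeds `steady_tol` is `oscillatory`; divergence,
non-finite values or integrator failure yield `unresolved`.

## Attractor enumeration and stability

`find_attractors` draws `n_samples` initial states (`x ~ U(0,1)`,
`η ~ U(0.5,1.5)`, both configurable, seeded), integrates each, and
deduplicates converged endpoints by max-norm distance in `x` only
(`dedup_tol = 1e-3`): the phenotype is the expression profile, and merged
trajectories may carry different η (their mean is stored, with a re-polish
of `x` at the stored η so the residual invariant holds).  Oscillatory
endpoints are deduplicated the same way for module-level reporting.

Stability is classified on the concentration subsystem at frozen η.  The
joint Jacobian is structurally degenerate at every fixed point (the η rows
vanish with `dx/dt`), so its zero eigenvalues say nothing about profile
robustness; freezing η asks whether the profile returns after a small
concentration perturbation.  `stable` requires all eigenvalue real parts
below `−eig_tol`, `degenerate` flags any real part within
`eig_tol = 1e-6` of zero (the numerical eigenvalue noise floor), anything
else is `unstable`.  Clamped nodes are excluded, so the Jacobian dimension
equals the number of free nodes.

## Landscape analysis

The attractor-by-node matrix is analyzed with PCA (reporting and plots),
agglomerative clustering (Euclidean, average linkage) and seeded K-means
(`k = 3`, k-means++-style init, 10 restarts, best inertia kept).  K-means
runs in full node space by default; `cluster_on_components` switches to
the leading principal components covering a requested variance fraction.
Domain size is the share of unique attractor profiles per cluster
(`proportions`), with basin tallies available separately on each
attractor.

Clusters are labeled by binarizing centroids at the per-node midpoint of
the observed range (flat nodes fall back to 0.5 — node scales depend on
the η each trajectory settled at, so absolute thresholds are avoided) and
scoring agreement with marker signatures.  The best match to the normal
signature is labeled `normal` (ties resolve to the lowest index, logged);
remaining clusters take the best-matching subtype signature, or
permutation-invariant `abnormal-k` fallbacks ranked by agreement.  Default
signatures encode the standard markers — normal epithelium: E-cadherin,
HNF4A, TGF-beta high with cyclins, NF-kB, VEGF low; intestinal subtype:
Wnt/beta-catenin-Cdx2; gastric/diffuse subtype: Sox2-Shh — and are
user-overridable; markers absent from the network are ignored.  **Caveat:**
with a single cluster the best match is labeled `normal` by construction,
so a 100% normal share on a collapsed (one-domain) landscape must be read
together with the centroid itself.

Functional modules (cell cycle, apoptosis, growth factors, adhesion,
angiogenesis, metabolism, inflammation, gastric differentiation by
default) are summarized per domain: ON when at least half the member
nodes exceed threshold, OFF otherwise, ON|OFF when any member node is
flagged oscillatory.

## Intervention screens

`enumerate_single` produces all `2N` single-node clamps; `sample_combos`
samples dual/triple clamp sets without replacement from the
`C(N,r)·2^r` space.  Each run (baseline included) re-enumerates the
landscape under its clamp set with a per-run seed spawned deterministically
from the master seed, refits K-means and relabels by signature — refitting
per run, with labels carried by signature matching rather than cluster
index, because cluster indices permute freely between runs.  Clamped nodes
stay in the feature matrix as constant columns so centroids remain
comparable with baseline signatures.  The score is the normal-labeled
share of unique profiles; ranking is by score, ties preferring fewer
targets, then lexicographic id.

`run_screen(reference=...)` replaces the per-run refit with
nearest-centroid assignment to a fitted baseline landscape.  This is the
right tool when the question is reproducibility of the *enumeration*: on
landscapes without genuinely separated domains (e.g. random networks),
per-run K-means boundary placement contributes several percentage points
of run-to-run variance that has nothing to do with the sampling itself.

## Expression comparison

Cohorts are genes-by-samples tables; preprocessing offers log2 and
per-gene z-scoring (zero-variance genes are dropped with a warning).
Samples are clustered with the same K-means machinery as attractors.
Model-data concordance discretizes both profiles into 4 categories —
three numeric levels splitting each profile's own range, plus an
oscillatory category — and reports the percentage of agreeing nodes
alongside the chance line `100/levels = 25%`.  Four categories (rather
than a binary scheme) are used precisely because the meaningful chance
baseline is 25%.  Multi-gene nodes aggregate by median for robustness to
outlier probes.  Level count and boundaries are configurable.  This
concordance definition is a declared reconstruction: it is the package's
own operationalization of profile agreement, not a transcription of any
particular published computation.

## Synthetic data

The generators provide every input the test path needs:

- `make_toggle_switch`: the canonical bistability motif; under fixed
  `η = 1` it has the two polarized attractors, the all-off attractor and
  two axis saddles (see above).
- `make_repressilator`: a 3-node inhibition ring fed by a self-sustaining
  source node (the in-form substitute for basal production; constitutive
  activity is always modeled as self-activation, never a basal-rate
  term).  The ring's symmetric state is Hopf-unstable only for slow
  degradation — at `n=3, a=10` roughly `η < 0.4` — so the oscillation
  fixture runs at fixed `η = 0.25` with initial concentrations in
  (0.3, 1), away from the all-off corner (`repressilator_params`).  With
  the degradation layer on, oscillations self-quench (see above), which
  is the layer's designed behaviour, not a fixture defect.
- `make_random_network(55, 253)`: a random signed network at the scale of
  a curated cancer core network, every node guaranteed at least one
  activator so none is trivially pinned at zero.
- `make_expression_cohort`: planted-cluster cohorts; defaults emulate the
  clinical structure used throughout — 111 tumor samples in two subtypes
  (56 + 55) plus 21 normal samples, group-exclusive marker blocks, i.i.d.
  Gaussian noise of scale `σ = 0.1` per gene on the log scale.

All generators are pure functions of parameters and seed.  What the
generators do **not** emulate: probe/batch effects, correlated noise,
realistic expression distributions, or a biologically meaningful random
topology.  Tests passing on these fixtures establish the machinery
(enumeration, clustering, labeling, screening, recovery at planted
separation), not biological claims about any particular network.

## Problem sizes and determinism

Default study sizes are chosen so a full landscape is minutes of work on
one CPU: 200 sampled initials for a landscape fit, 100–1000 for screens
depending on the precision needed on domain shares (a share `p` estimated
from `n` unique profiles carries binomial error `√(p(1−p)/n)`; at
`n = 1000` about 1.3 points).  Oracle-equivalence checks enumerate all
two-node signed patterns (9 cross-edge combinations, with and without
self-activation) against a batched fixed-step RK4 grid oracle.  Every
stochastic step takes an explicit seed; the pipeline spawns per-stage and
per-run seeds deterministically from one master seed and records them in
the run manifest, making TSV outputs byte-reproducible from
(config, seed).

## Known limitations

- The curated 55-node gastric network itself is an input, not part of the
  package; shipped fixtures are motifs and random networks, and headline
  percentages on random fixtures are properties of the machinery, not
  reproductions of any clinical landscape.
- The all-off attractor is a structural feature of the basal-free Hill
  law; analyses that consider it biologically meaningless should either
  restrict initial conditions away from its basin or filter it from the
  ensemble before clustering.
- Stability classification at frozen η ignores the neutral directions
  along the fixed-point manifold; profiles are robust to concentration
  perturbations but η-perturbations slide along the manifold by design.
- Oscillation detection is an amplitude test at the horizon, not spectral
  analysis: slow transients that have not converged by `t_max` can be
  flagged oscillatory.  Raising `t_max` sharpens the distinction.
- No continuation/bifurcation analysis, no transition rates or landscape
  potentials, no stochastic (noise-driven) simulation: randomness enters
  only through initial conditions.
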