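"""Synthetic inputs: motif networks and planted expression cohorts.

Everything the pipeline consumes can be generated here so the full test
path runs without downloads: two-node toggle switches with known
bistability, a repressilator-style oscillation fixture, random signed
networks at the scale of the curated gastric network (55 nodes, 253
edges), and labeled expression cohorts with planted three-cluster
structure (two tumor subtypes plus a normal group, 111 tumor / 21 normal
samples by default).  All generators are pure functions of their
parameters and seed.

Motifs use the pipeline's global Hill constants (n = 3, a = 10) so the
fixtures exercise exactly the production law used in production runs, and
constitutive activity is modeled as self-activation edges, staying within
the Hill functional form (no basal-rate terms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import DynamicsParams
from .expression import ExpressionMatrix
from .netspec import NetworkSpec, network_from_edges


def make_toggle_switch() -> NetworkSpec:
    """Two mutually inhibiting, self-activating nodes.

    The classic bistable motif: with the default Hill constants and fixed
    degradation (eta = 1) the x-subsystem has exactly two stable fixed
    points (A high / B low and its mirror image) plus an unstable saddle on
    the diagonal.
    """
    return network_from_edges(
        [
            ("A", "A", 1),
            ("B", "B", 1),
            ("A", "B", -1),
            ("B", "A", -1),
        ]
    )


def make_repressilator() -> NetworkSpec:
    """Three-node inhibition ring with a constitutive source.

    Each ring node is activated by a self-sustaining source node ``S``
    (self-activation plus feedback activation from the ring, the in-form
    substitute for basal production) and inhibited by its predecessor.
    In the oscillatory degradation regime (see
    :func:`repressilator_params`) the symmetric fixed point is
    Hopf-unstable and trajectories settle onto a limit cycle.
    """
    edges = [("S", "S", 1)]
    ring = ["R1", "R2", "R3"]
    for r in ring:
        edges.append(("S", r, 1))
        edges.append((r, "S", 1))
    for i, r in enumerate(ring):
        edges.append((r, ring[(i + 1) % 3], -1))
    return network_from_edges(edges)


def repressilator_params(**overrides) -> DynamicsParams:
    """Dynamics parameters in the oscillatory regime of the ring.

    Sustained oscillation needs slow degradation: at the default Hill
    constants the ring's symmetric state is Hopf-unstable only for
    degradation rates below roughly 0.4, so the fixture fixes eta = 0.25.
    (With the degradation layer enabled, eta drifts upward whenever
    dx/dt != 0 on average, which actively quenches oscillations — that is
    the layer's purpose.)  Initial concentrations start away from the
    all-off corner so every trajectory reaches the active regime.
    """
    kw = dict(
        eta_dynamics=False,
        eta_fixed=0.25,
        x_init=(0.3, 1.0),
        t_max=400.0,
    )
    kw.update(overrides)
    return DynamicsParams(**kw)


def make_random_network(
    n_nodes: int,
    n_edges: int,
    seed: int | None = 0,
    ensure_activator: bool = True,
    p_activation: float = 0.5,
) -> NetworkSpec:
    """Random signed directed network, optionally with no dead nodes.

    With ``ensure_activator`` every node receives at least one activating
    edge (otherwise its production is identically zero and it is pinned at
    the origin), which requires ``n_edges >= n_nodes``.  Remaining edges
    are drawn uniformly over unused (source, target) pairs with activation
    probability ``p_activation``.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if n_edges > n_nodes * n_nodes:
        raise ValueError("n_edges exceeds number of possible (source, target) pairs")
    if ensure_activator and n_edges < n_nodes:
        raise ValueError("ensure_activator requires n_edges >= n_nodes")
    rng = np.random.default_rng(seed)
    width = len(str(n_nodes))
    nodes = [f"N{i + 1:0{width}d}" for i in range(n_nodes)]
    used: set[tuple[int, int]] = set()
    edges: list[tuple[str, str, int]] = []
    if ensure_activator:
        for tgt in range(n_nodes):
            src = int(rng.integers(0, n_nodes))
            used.add((src, tgt))
            edges.append((nodes[src], nodes[tgt], 1))
    while len(edges) < n_edges:
        src = int(rng.integers(0, n_nodes))
        tgt = int(rng.integers(0, n_nodes))
        if (src, tgt) in used:
            continue
        used.add((src, tgt))
        sign = 1 if rng.random() < p_activation else -1
        edges.append((nodes[src], nodes[tgt], sign))
    return network_from_edges(edges, nodes=nodes)


@dataclass
class CohortSpec:
    """Recipe for a labeled expression cohort with planted clusters.

    Defaults emulate the clinical cohort structure used throughout:
    111 tumor samples split into two subtypes plus 21 normal samples,
    i.i.d. Gaussian noise of scale ``sigma`` per gene on the log scale.
    """

    groups: dict[str, int] = field(
        default_factory=lambda: {"tumor-a1": 56, "tumor-a3": 55, "normal": 21}
    )
    profiles: dict[str, np.ndarray] | None = None
    n_genes: int = 40
    sigma: float = 0.1
    seed: int | None = 0

    def __post_init__(self) -> None:
        if any(size < 1 for size in self.groups.values()):
            raise ValueError("group sizes must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def default_group_profiles(
    groups: list[str], n_genes: int, seed: int | None = 0
) -> dict[str, np.ndarray]:
    """Well-separated binary-block mean profiles, one per group.

    Each group gets an exclusive block of marker genes set high (level 1)
    on a low background (level 0), mimicking subtype marker panels.
    """
    rng = np.random.default_rng(seed)
    block = max(1, n_genes // (len(groups) + 1))
    profiles = {}
    for gi, name in enumerate(groups):
        p = np.zeros(n_genes)
        lo = gi * block
        p[lo : lo + block] = 1.0
        p += 0.05 * rng.standard_normal(n_genes)  # mild per-gene offsets
        profiles[name] = p
    return profiles


def make_expression_cohort(
    cohort: CohortSpec, gene_names: list[str] | None = None
) -> tuple[ExpressionMatrix, pd.Series]:
    """Draw a cohort: per-sample profile = group mean + N(0, sigma) per gene.

    Returns the matrix and the true group labels (also attached to the
    matrix) for recovery tests.  With ``sigma = 0`` every sample equals its
    group profile exactly.
    """
    rng = np.random.default_rng(cohort.seed)
    group_names = list(cohort.groups)
    profiles = cohort.profiles or default_group_profiles(
        group_names, cohort.n_genes, seed=cohort.seed
    )
    n_genes = len(next(iter(profiles.values())))
    for name in group_names:
        if name not in profiles:
            raise ValueError(f"no profile for group {name!r}")
        if len(profiles[name]) != n_genes:
            raise ValueError("group profiles must have equal length")
    genes = gene_names or [f"G{i + 1:03d}" for i in range(n_genes)]
    cols, labels, data = [], [], []
    for name in group_names:
        mean = np.asarray(profiles[name], dtype=float)
        for j in range(cohort.groups[name]):
            cols.append(f"{name}-{j + 1:03d}")
            labels.append(name)
            data.append(mean + rng.normal(0.0, cohort.sigma, size=n_genes))
    values = pd.DataFrame(np.array(data).T, index=genes, columns=cols)
    lab = pd.Series(labels, index=cols, name="group")
    return ExpressionMatrix(values, lab), lab
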