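"""In-silico intervention screens.

An intervention clamps one, two or three nodes to 0 (full inhibition) or 1
(full activation), the attractor landscape is re-enumerated under the
clamp, re-clustered (K-means, k = 3) and re-labeled against the phenotype
signature, and the intervention is scored by the percentage of unique
attractor profiles falling in the normal-labeled domain.  A network of N
nodes admits 2N single-agent interventions; dual and triple combinations
are sampled without replacement from the C(N, r) * 2^r combination space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attractors import find_attractors
from .dynamics import ClampSet, DynamicsParams
from .landscape import LandscapeModel, build_landscape
from .netspec import NetworkSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerturbationSpec:
    """An ordered set of (node, clamp value) pairs; order 0 is baseline."""

    clamps: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        nodes = [n for n, _ in self.clamps]
        if len(set(nodes)) != len(nodes):
            raise ValueError("clamped nodes must be distinct")

    @property
    def order(self) -> int:
        return len(self.clamps)

    @property
    def id(self) -> str:
        if not self.clamps:
            return "baseline"
        return ";".join(f"{n}={v:g}" for n, v in self.clamps)

    def as_dict(self) -> dict[str, float]:
        return dict(self.clamps)

    def validate(self, spec: NetworkSpec) -> None:
        ClampSet(self.as_dict(), spec, binary_only=False)


@dataclass
class PerturbationResult:
    """Landscape outcome of one intervention."""

    perturbation: PerturbationSpec
    proportions: pd.DataFrame  # cluster, count, percent, label
    normal_percent: float
    n_unique: int
    n_samples: int
    seed: int | None
    landscape: LandscapeModel | None = None

    @property
    def id(self) -> str:
        return self.perturbation.id


def enumerate_single(spec: NetworkSpec) -> list[PerturbationSpec]:
    """All 2N single-agent interventions, in node order, clamp 0 before 1."""
    return [
        PerturbationSpec(((node, float(v)),)) for node in spec.nodes for v in (0, 1)
    ]


def combo_space_size(n_nodes: int, order: int) -> int:
    return comb(n_nodes, order) * 2**order


def sample_combos(
    spec: NetworkSpec, order: int, n: int, seed: int | None = 0
) -> list[PerturbationSpec]:
    """Sample ``n`` distinct order-r interventions without replacement."""
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    space = combo_space_size(spec.n_nodes, order)
    if n > space:
        raise ValueError(f"n={n} exceeds combination space of size {space}")
    rng = np.random.default_rng(seed)
    chosen: dict[tuple, None] = {}
    nodes = spec.nodes
    while len(chosen) < n:
        idx = tuple(sorted(rng.choice(spec.n_nodes, size=order, replace=False)))
        vals = tuple(float(v) for v in rng.integers(0, 2, size=order))
        chosen.setdefault((idx, vals))
    return [
        PerturbationSpec(tuple((nodes[i], v) for i, v in zip(idx, vals)))
        for idx, vals in chosen
    ]


def run_screen(
    spec: NetworkSpec,
    perturbations: Sequence[PerturbationSpec],
    params: DynamicsParams | None = None,
    n_samples: int = 200,
    seed: int | None = 0,
    signature: Mapping[str, int] | None = None,
    subtype_signatures: Mapping[str, Mapping[str, int]] | None = None,
    k: int = 3,
    restarts: int = 10,
    include_baseline: bool = True,
    keep_landscapes: bool = False,
    reference: LandscapeModel | None = None,
) -> list[PerturbationResult]:
    """Score each intervention by its normal-domain share.

    Every run (baseline included) re-enumerates attractors under its clamp
    set with a deterministic per-run seed spawned from the master seed, then
    re-fits K-means and re-labels clusters by the phenotype signature.
    Clamped nodes stay in the feature space as constant columns so that
    centroids remain comparable with the baseline signature.

    When ``reference`` is given (a fitted baseline landscape), K-means is
    not refit: each attractor is assigned to the nearest reference centroid
    and the reference labels are reused.  Domain shares are then defined by
    a run-independent partition of state space, which isolates the
    enumeration's own sampling variability from clustering variability.
    """
    params = params or DynamicsParams()
    for p in perturbations:
        p.validate(spec)  # fail fast, before any simulation
    todo = list(perturbations)
    if include_baseline:
        todo = [PerturbationSpec(())] + todo
    results: list[PerturbationResult] = []
    for idx, pert in enumerate(todo):
        run_seed = _spawn_seed(seed, idx)
        ensemble = find_attractors(
            spec,
            params,
            clamps=pert.as_dict(),
            n_samples=n_samples,
            seed=run_seed,
        )
        if ensemble.n_unique == 0:
            logger.warning("%s: no fixed-point attractors; normal share 0", pert.id)
            results.append(
                PerturbationResult(pert, proportions=pd.DataFrame(), normal_percent=0.0,
                                   n_unique=0, n_samples=n_samples, seed=run_seed)
            )
            continue
        if reference is not None:
            results.append(
                _assign_to_reference(pert, ensemble, reference, n_samples, run_seed)
            )
            continue
        land = build_landscape(
            ensemble,
            k=k,
            seed=run_seed,
            restarts=restarts,
            signature=signature,
            subtype_signatures=subtype_signatures,
        )
        results.append(
            PerturbationResult(
                perturbation=pert,
                proportions=land.proportions,
                normal_percent=land.normal_percent,
                n_unique=ensemble.n_unique,
                n_samples=n_samples,
                seed=run_seed,
                landscape=land if keep_landscapes else None,
            )
        )
    return results


def _assign_to_reference(
    pert: PerturbationSpec,
    ensemble,
    reference: LandscapeModel,
    n_samples: int,
    run_seed: int | None,
) -> PerturbationResult:
    X = ensemble.feature_matrix()
    cents = reference.kmeans.centroids
    d = np.linalg.norm(X[:, None, :] - cents[None, :, :], axis=2)
    assign = d.argmin(axis=1)
    counts = np.bincount(assign, minlength=cents.shape[0])
    pct = 100.0 * counts / counts.sum()
    tab = pd.DataFrame(
        {
            "cluster": np.arange(cents.shape[0]),
            "count": counts,
            "percent": pct,
            "label": reference.labels,
        }
    )
    normal = tab.loc[tab["label"] == "normal", "percent"]
    return PerturbationResult(
        perturbation=pert,
        proportions=tab,
        normal_percent=float(normal.iloc[0]) if len(normal) else 0.0,
        n_unique=ensemble.n_unique,
        n_samples=n_samples,
        seed=run_seed,
    )


def _spawn_seed(master: int | None, idx: int) -> int | None:
    if master is None:
        return None
    ss = np.random.SeedSequence([int(master), idx])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rank_interventions(results: Sequence[PerturbationResult]) -> pd.DataFrame:
    """Ranked table, best normal share first; ties favor fewer targets."""
    if not results:
        raise ValueError("no results to rank")
    rows = [
        {
            "id": r.id,
            "order": r.perturbation.order,
            "normal_percent": r.normal_percent,
            "n_unique": r.n_unique,
            "n_samples": r.n_samples,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["normal_percent", "order", "id"],
        ascending=[False, True, True],
        ignore_index=True,
    )
    return df


def plot_screen(results: Sequence[PerturbationResult], ax=None):
    """Bar chart of normal-domain percentage per intervention."""
    import matplotlib.pyplot as plt

    ranked = rank_interventions(results)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.25 * len(ranked)), 3))
    ax.bar(range(len(ranked)), ranked["normal_percent"])
    ax.set_xticks(range(len(ranked)))
    ax.set_xticklabels(ranked["id"], rotation=90, fontsize=6)
    ax.set_ylabel("normal states (%)")
    return ax
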