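"""Model/Results surface over the simulation and landscape machinery.

:class:`EndogenousNetworkModel` is constructed from a signed interaction
network (plus dynamics parameters and phenotype signatures); ``fit()``
samples the attractor landscape and returns a :class:`LandscapeResults`
carrying the attractor ensemble, the clustered landscape, domain
proportions and labels, with ``summary()``, ``plot()`` and ``save()``.
Perturbation screens hang off the model as ``screen()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attractors import AttractorEnsemble, find_attractors
from .dynamics import DynamicsParams
from .landscape import (
    DEFAULT_MODULES,
    NORMAL_SIGNATURE,
    SUBTYPE_SIGNATURES,
    LandscapeModel,
    build_landscape,
    module_activity,
)
from .netspec import NetworkSpec, network_from_edges, parse_network, validate_network
from .perturb import (
    PerturbationResult,
    PerturbationSpec,
    enumerate_single,
    rank_interventions,
    run_screen,
    sample_combos,
)


class EndogenousNetworkModel:
    """Attractor-landscape model of an endogenous molecular network.

    Parameters
    ----------
    network
        The signed interaction network.
    params
        Dynamics constants; defaults to the standard Hill constants
        (n = 3, a = 10) with the degradation layer enabled.
    signature, subtype_signatures
        Phenotype marker signatures used to label clusters; markers absent
        from the network are ignored.
    modules
        Functional-module map for module-level ON/OFF summaries.
    """

    def __init__(
        self,
        network: NetworkSpec,
        params: DynamicsParams | None = None,
        signature: Mapping[str, int] | None = None,
        subtype_signatures: Mapping[str, Mapping[str, int]] | None = None,
        modules: Mapping[str, Sequence[str]] | None = None,
    ) -> None:
        self.network = network
        self.params = params or DynamicsParams()
        self.signature = dict(signature) if signature is not None else dict(NORMAL_SIGNATURE)
        self.subtype_signatures = (
            {k: dict(v) for k, v in subtype_signatures.items()}
            if subtype_signatures is not None
            else {k: dict(v) for k, v in SUBTYPE_SIGNATURES.items()}
        )
        self.modules = {k: list(v) for k, v in (modules or DEFAULT_MODULES).items()}
        self.validation = validate_network(network)

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_edgelist(cls, path: str | Path, **kwargs) -> "EndogenousNetworkModel":
        """Build from a TSV interaction table (source, target, sign)."""
        return cls(parse_network(path), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "EndogenousNetworkModel":
        """Build from a dataframe with source/target/sign columns."""
        edges = [
            (str(r["source"]), str(r["target"]), int(r["sign"])) for _, r in df.iterrows()
        ]
        return cls(network_from_edges(edges), **kwargs)

    # -- estimation ------------------------------------------------------

    def fit(
        self,
        n_samples: int = 200,
        seed: int | None = 0,
        clamps: Mapping[str, float] | None = None,
        k: int = 3,
        restarts: int = 10,
    ) -> "LandscapeResults":
        """Sample the attractor landscape and cluster it into domains."""
        ensemble = find_attractors(
            self.network, self.params, clamps=clamps, n_samples=n_samples, seed=seed
        )
        landscape = None
        if ensemble.n_unique > 0:
            landscape = build_landscape(
                ensemble,
                k=k,
                seed=seed,
                restarts=restarts,
                signature=self.signature,
                subtype_signatures=self.subtype_signatures,
            )
        return LandscapeResults(
            model=self, ensemble=ensemble, landscape=landscape, seed=seed, clamps=dict(clamps or {})
        )

    # -- screening -------------------------------------------------------

    def screen(
        self,
        order: int = 1,
        n_combos: int | None = None,
        perturbations: Sequence[PerturbationSpec] | None = None,
        n_samples: int = 200,
        seed: int | None = 0,
        k: int = 3,
        restarts: int = 10,
    ) -> "ScreenResults":
        """Run a clamp-intervention screen and rank by normal-domain share."""
        if perturbations is None:
            if order == 1:
                perturbations = enumerate_single(self.network)
            else:
                if n_combos is None:
                    raise ValueError("n_combos required for order > 1")
                perturbations = sample_combos(self.network, order, n_combos, seed=seed)
        results = run_screen(
            self.network,
            perturbations,
            params=self.params,
            n_samples=n_samples,
            seed=seed,
            signature=self.signature,
            subtype_signatures=self.subtype_signatures,
            k=k,
            restarts=restarts,
        )
        return ScreenResults(model=self, results=results, seed=seed)


@dataclass
class LandscapeResults:
    """Fitted attractor landscape: estimates, uncertainties, diagnostics."""

    model: EndogenousNetworkModel
    ensemble: AttractorEnsemble
    landscape: LandscapeModel | None
    seed: int | None
    clamps: dict = field(default_factory=dict)

    @property
    def proportions(self) -> pd.DataFrame:
        if self.landscape is None:
            return pd.DataFrame(columns=["cluster", "count", "percent", "label"])
        return self.landscape.proportions

    @property
    def normal_percent(self) -> float:
        return self.landscape.normal_percent if self.landscape is not None else 0.0

    @property
    def centroids(self) -> pd.DataFrame:
        if self.landscape is None:
            return pd.DataFrame(columns=self.model.network.nodes)
        return pd.DataFrame(
            self.landscape.kmeans.centroids,
            columns=self.model.network.nodes,
            index=self.landscape.labels,
        )

    def module_table(self) -> pd.DataFrame:
        """Per-cluster functional-module ON/OFF summary (ON|OFF when any
        member node oscillates in the domain's oscillatory profiles)."""
        if self.landscape is None:
            return pd.DataFrame()
        spec = self.model.network
        osc_any = np.zeros(spec.n_nodes, dtype=bool)
        for a in self.ensemble.oscillatory_profiles:
            if a.node_oscillating is not None:
                osc_any |= a.node_oscillating
        rows = {}
        from .attractors import Attractor

        for label, centroid in zip(self.landscape.labels, self.landscape.kmeans.centroids):
            pseudo = Attractor(
                x=centroid,
                eta=np.ones_like(centroid),
                stability="stable",
                node_oscillating=osc_any if osc_any.any() else None,
            )
            rows[label] = module_activity(
                pseudo,
                self.model.modules_present(),
                spec,
                threshold=_mid_threshold(self.landscape.features),
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit report."""
        e = self.ensemble
        lines = [
            "Endogenous network attractor landscape",
            "=" * 54,
            f"nodes: {self.model.network.n_nodes}    edges: {self.model.network.n_edges}"
            f"    coupled ODEs: {2 * self.model.network.n_nodes}",
            f"sampled initials: {e.n_samples}    seed: {self.seed}",
            f"converged: {e.n_converged}    oscillatory: {e.n_oscillatory}"
            f"    unresolved: {e.n_unresolved}",
            f"unique stable profiles: {e.n_unique}",
        ]
        if self.clamps:
            lines.append("clamps: " + ", ".join(f"{k}={v:g}" for k, v in self.clamps.items()))
        if self.landscape is not None:
            lines.append("-" * 54)
            lines.append("domain proportions (share of unique profiles):")
            for _, row in self.proportions.iterrows():
                lines.append(
                    f"  cluster {int(row['cluster'])} [{row['label']}]: "
                    f"{int(row['count'])} points, {row['percent']:.2f}%"
                )
            lines.append(f"normal-domain share: {self.normal_percent:.2f}%")
        return "\n".join(lines)

    def plot(self, ax=None):
        if self.landscape is None:
            raise ValueError("no landscape to plot (no attractors)")
        return self.landscape.plot(ax=ax)

    def save(self, outdir: str | Path) -> Path:
        """Write attractors, cluster table, centroids and a JSON summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.ensemble.save(outdir / "attractors.tsv")
        if self.landscape is not None:
            self.landscape.cluster_table().to_csv(
                outdir / "clusters.tsv", sep="\t", index=False, float_format="%.10g"
            )
            self.centroids.to_csv(outdir / "centroids.tsv", sep="\t", float_format="%.10g")
            summary = {
                "counts": self.proportions["count"].tolist(),
                "percent": self.proportions["percent"].tolist(),
                "labels": self.proportions["label"].tolist(),
                "normal_percent": self.normal_percent,
                "seed": self.seed,
                "clamps": self.clamps,
            }
            (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        return outdir


@dataclass
class ScreenResults:
    """Ranked outcome of an intervention screen."""

    model: EndogenousNetworkModel
    results: list[PerturbationResult]
    seed: int | None

    @property
    def baseline(self) -> PerturbationResult | None:
        for r in self.results:
            if r.perturbation.order == 0:
                return r
        return None

    def ranked(self) -> pd.DataFrame:
        return rank_interventions(self.results)

    def summary(self) -> str:
        df = self.ranked()
        lines = [
            "Intervention screen (normal-domain share per clamp set)",
            "=" * 54,
            f"interventions: {len(df)}    seed: {self.seed}",
        ]
        base = self.baseline
        if base is not None:
            lines.append(f"baseline normal share: {base.normal_percent:.2f}%")
        lines.append("-" * 54)
        for _, row in df.head(10).iterrows():
            lines.append(f"  {row['id']:<30s} {row['normal_percent']:6.2f}%")
        return "\n".join(lines)

    def plot(self, ax=None):
        from .perturb import plot_screen

        return plot_screen(self.results, ax=ax)

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.ranked().to_csv(outdir / "screen.tsv", sep="\t", index=False, float_format="%.10g")
        detail = [
            {
                "id": r.id,
                "order": r.perturbation.order,
                "normal_percent": r.normal_percent,
                "n_unique": r.n_unique,
                "n_samples": r.n_samples,
                "seed": r.seed,
                "proportions": r.proportions.to_dict(orient="records")
                if len(r.proportions)
                else [],
            }
            for r in self.results
        ]
        (outdir / "screen.json").write_text(json.dumps(detail, indent=2))
        return outdir


def _mid_threshold(features: np.ndarray) -> np.ndarray:
    from .landscape import binarize_threshold

    return binarize_threshold(features)


def _modules_present(model: EndogenousNetworkModel) -> dict[str, list[str]]:
    spec = model.network
    out = {}
    for name, members in model.modules.items():
        present = [m for m in members if m in spec]
        if present:
            out[name] = present
    return out


# bound as a method for convenience
EndogenousNetworkModel.modules_present = _modules_present
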