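"""Pipeline orchestration: staged runs with a manifest.

A :class:`RunConfig` (flat key-value document, YAML on disk) drives the
stages ``synth`` -> ``simulate`` -> ``cluster`` -> ``screen`` ->
``compare``; every stage writes plain-text artifacts into the run
directory and the manifest records the config digest, the per-stage seeds
spawned from the master seed, package versions and timings.  Identical
(config, seed) produce byte-identical TSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dynamics import DynamicsParams
from .expression import concordance, cluster_samples, write_expression
from .landscape import NORMAL_SIGNATURE, signature_from_centroid
from .model import EndogenousNetworkModel
from .netspec import parse_network, write_network
from .perturb import enumerate_single, sample_combos
from .synthetic import CohortSpec, make_expression_cohort, make_random_network

ALL_STAGES = ("synth", "simulate", "cluster", "screen", "compare")


@dataclass
class RunConfig:
    """Validated flat configuration for a pipeline run."""

    # dynamics
    hill_n: float = 3.0
    hill_a: float = 10.0
    kappa: float = 1.5
    eta_floor: float = 1e-3
    eta_dynamics: bool = True
    eta_fixed: float = 1.0
    t_max: float = 500.0
    steady_tol: float = 1e-8
    window: float = 10.0
    # sampling
    n_samples: int = 200
    x_init: tuple[float, float] = (0.0, 1.0)
    eta_init: tuple[float, float] = (0.5, 1.5)
    # clustering
    k: int = 3
    restarts: int = 10
    # screening
    screen_order: int = 1
    n_combos: int = 20
    screen_samples: int = 100
    # synth stage
    synth_nodes: int = 55
    synth_edges: int = 253
    cohort_sigma: float = 0.1
    # inputs
    network: str | None = None
    signature: str | None = None
    expression: str | None = None
    expression_labels: str | None = None
    # run control
    seed: int = 0
    out: str = "run"

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.screen_samples < 1:
            raise ValueError("sample counts must be >= 1")
        if self.k < 1 or self.restarts < 1:
            raise ValueError("k and restarts must be >= 1")
        if self.screen_order not in (1, 2, 3):
            raise ValueError("screen_order must be 1, 2 or 3")
        if not 0 <= self.cohort_sigma:
            raise ValueError("cohort_sigma must be >= 0")
        self.x_init = tuple(self.x_init)
        self.eta_init = tuple(self.eta_init)
        DynamicsParams(**self._dynamics_kwargs())  # bounds checked there

    def _dynamics_kwargs(self) -> dict:
        names = {
            "hill_n", "hill_a", "kappa", "eta_floor", "eta_dynamics",
            "eta_fixed", "t_max", "steady_tol", "window", "x_init", "eta_init",
        }
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name in names}

    def dynamics_params(self) -> DynamicsParams:
        return DynamicsParams(**self._dynamics_kwargs())

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ValueError("config must be a flat key-value document")
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ALL_STAGES) -> Path:
    """Execute the requested stages; returns the run directory."""
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "endonet_version": __version__,
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "master_seed": config.seed,
        "stages": {},
    }
    params = config.dynamics_params()

    # resolve inputs up front so missing files fail before any compute
    network_path = Path(config.network) if config.network else None
    if network_path is not None and not network_path.exists():
        raise FileNotFoundError(f"network file not found: {network_path}")
    for attr in ("signature", "expression", "expression_labels"):
        p = getattr(config, attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{attr} file not found: {p}")

    net = None
    results = None
    timings: dict[str, float] = {}

    if "synth" in stages:
        t0 = time.perf_counter()
        seed = stage_seed(config.seed, "synth")
        net = make_random_network(config.synth_nodes, config.synth_edges, seed=seed)
        write_network(net, outdir / "network.tsv")
        cohort = CohortSpec(sigma=config.cohort_sigma, seed=seed)
        matrix, labels = make_expression_cohort(cohort)
        write_expression(matrix, outdir / "expression.tsv", outdir / "expression_labels.tsv")
        manifest["stages"]["synth"] = {"seed": seed, "nodes": net.n_nodes, "edges": net.n_edges}
        timings["synth"] = time.perf_counter() - t0

    if net is None and network_path is not None:
        net = parse_network(network_path)
    if net is None and any(s in stages for s in ("simulate", "cluster", "screen")):
        raise ValueError("no network: provide config.network or include the synth stage")

    signature = None
    if config.signature:
        sig_doc = yaml.safe_load(Path(config.signature).read_text())
        signature = {str(k): int(v) for k, v in sig_doc.items()}

    model = None
    if net is not None:
        model = EndogenousNetworkModel(net, params=params, signature=signature or NORMAL_SIGNATURE)

    if "simulate" in stages or "cluster" in stages:
        t0 = time.perf_counter()
        seed = stage_seed(config.seed, "simulate")
        results = model.fit(n_samples=config.n_samples, seed=seed,
                            k=config.k, restarts=config.restarts)
        results.ensemble.save(outdir / "attractors.tsv")
        manifest["stages"]["simulate"] = {
            "seed": seed,
            "n_samples": config.n_samples,
            "n_unique": results.ensemble.n_unique,
        }
        timings["simulate"] = time.perf_counter() - t0

    if "cluster" in stages and results is not None and results.landscape is not None:
        t0 = time.perf_counter()
        results.save(outdir)
        manifest["stages"]["cluster"] = {
            "k": config.k,
            "labels": results.landscape.labels,
            "normal_percent": results.normal_percent,
        }
        timings["cluster"] = time.perf_counter() - t0

    if "screen" in stages:
        t0 = time.perf_counter()
        seed = stage_seed(config.seed, "screen")
        if signature is None and results is not None and results.landscape is not None:
            # no curated panel: screen against the smallest baseline domain
            tab = results.proportions.sort_values("count", ignore_index=True)
            ref = int(tab["cluster"].iloc[0])
            model.signature = dict(
                signature_from_centroid(
                    results.landscape.kmeans.centroids[ref], net,
                    threshold=np.median(results.landscape.features, axis=0),
                )
            )
        if config.screen_order == 1:
            perts = enumerate_single(net)[: 2 * config.n_combos]
        else:
            perts = sample_combos(net, config.screen_order, config.n_combos, seed=seed)
        screen = model.screen(
            perturbations=perts,
            n_samples=config.screen_samples,
            seed=seed,
            k=config.k,
            restarts=config.restarts,
        )
        screen.save(outdir)
        manifest["stages"]["screen"] = {
            "seed": seed,
            "n_perturbations": len(perts),
            "best": screen.ranked().iloc[0]["id"],
        }
        timings["screen"] = time.perf_counter() - t0

    if "compare" in stages:
        t0 = time.perf_counter()
        seed = stage_seed(config.seed, "compare")
        expr_path = (
            Path(config.expression) if config.expression else outdir / "expression.tsv"
        )
        if expr_path.exists():
            from .expression import load_expression

            label_path = config.expression_labels or (
                outdir / "expression_labels.tsv"
                if (outdir / "expression_labels.tsv").exists()
                else None
            )
            matrix = load_expression(expr_path, label_path)
            assign, centroids, _ = cluster_samples(matrix, k=config.k, seed=seed,
                                                   restarts=config.restarts)
            comp: dict = {"seed": seed, "k": config.k,
                          "cluster_sizes": np.bincount(assign, minlength=config.k).tolist()}
            if results is not None and results.landscape is not None:
                pairs = []
                for mc in results.landscape.kmeans.centroids:
                    best = max(
                        (concordance(mc[: centroids.shape[1]], dc[: len(mc)])
                         ["agreement_percent"]
                         for dc in centroids),
                        default=0.0,
                    )
                    pairs.append(best)
                comp["best_concordance_percent"] = pairs
            (outdir / "compare.json").write_text(json.dumps(comp, indent=2))
            manifest["stages"]["compare"] = comp
        timings["compare"] = time.perf_counter() - t0

    manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
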