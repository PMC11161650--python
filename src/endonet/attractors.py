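"""Attractor enumeration from random initial conditions.

The state space is sampled with many random initial conditions (uniform
concentrations, uniform initial degradation rates), each trajectory is
integrated to its asymptotic fate, and converged endpoints are deduplicated
by concentration-profile distance.  Because the degradation layer makes the
final degradation rates trajectory-dependent, distinct initial conditions
generally land on distinct points of the fixed-point manifold: each unique
concentration profile is kept as one attractor (its "phenotypical profile")
and its basin tally counts the trajectories that reached it.

Linear stability is judged on the concentration subsystem at frozen
degradation rates.  The joint (x, eta) Jacobian is structurally degenerate
at every fixed point — the eta rows vanish identically with dx/dt, so the
eta directions contribute zero eigenvalues that say nothing about whether
the expression profile is robust.  Freezing eta asks the biologically
meaningful question: does the profile return after a small perturbation of
the concentrations?
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.linalg import eigvals

from .dynamics import ClampSet, CompiledDynamics, DynamicsParams, SystemState, integrate_to_steady
from .netspec import NetworkSpec

logger = logging.getLogger(__name__)

Stability = Literal["stable", "unstable", "degenerate"]

DEDUP_TOL = 1e-3
EIG_TOL = 1e-6


@dataclass
class Attractor:
    """One deduplicated asymptotic state of the sampled dynamics."""

    x: np.ndarray
    eta: np.ndarray
    stability: Stability
    basin_count: int = 1
    oscillatory: bool = False
    node_oscillating: np.ndarray | None = None
    residual: float = np.nan
    eigenvalues: np.ndarray | None = None

    @property
    def state(self) -> SystemState:
        return SystemState(self.x, self.eta)


@dataclass
class AttractorEnsemble:
    """Deduplicated attractors plus sampling bookkeeping."""

    spec: NetworkSpec
    attractors: list[Attractor]
    oscillatory_profiles: list[Attractor]
    n_samples: int
    n_converged: int
    n_oscillatory: int
    n_unresolved: int
    seed: int | None
    dedup_tol: float = DEDUP_TOL
    clamps: dict = field(default_factory=dict)

    @property
    def n_unique(self) -> int:
        return len(self.attractors)

    def stable(self) -> list[Attractor]:
        return [a for a in self.attractors if a.stability == "stable"]

    def feature_matrix(self, include_oscillatory: bool = False) -> np.ndarray:
        """Attractor-by-node concentration matrix for landscape analysis."""
        rows = [a.x for a in self.attractors]
        if include_oscillatory:
            rows += [a.x for a in self.oscillatory_profiles]
        if not rows:
            return np.empty((0, self.spec.n_nodes))
        return np.vstack(rows)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.attractors + self.oscillatory_profiles:
            row = dict(zip(self.spec.nodes, a.x))
            row["stability"] = a.stability
            row["basin_count"] = a.basin_count
            row["oscillatory"] = a.oscillatory
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> Path:
        """Write the attractor table (TSV) with a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        meta = {
            "n_samples": self.n_samples,
            "n_converged": self.n_converged,
            "n_oscillatory": self.n_oscillatory,
            "n_unresolved": self.n_unresolved,
            "n_unique": self.n_unique,
            "seed": self.seed,
            "dedup_tol": self.dedup_tol,
            "clamps": self.clamps,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))
        return path


def sample_initials(
    n: int,
    spec: NetworkSpec,
    params: DynamicsParams | None = None,
    seed: int | None = None,
    clamps: Mapping[str, float] | ClampSet | None = None,
) -> list[SystemState]:
    """Draw ``n`` random initial states; clamped coordinates are preset."""
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or DynamicsParams()
    cs = clamps if isinstance(clamps, ClampSet) else ClampSet(clamps, spec)
    rng = np.random.default_rng(seed)
    lo_x, hi_x = params.x_init
    lo_e, hi_e = params.eta_init
    states = []
    for _ in range(n):
        x = cs.apply(rng.uniform(lo_x, hi_x, size=spec.n_nodes))
        eta = rng.uniform(lo_e, hi_e, size=spec.n_nodes)
        states.append(SystemState(x, eta))
    return states


def classify_stability(
    attractor: Attractor | SystemState,
    spec: NetworkSpec,
    params: DynamicsParams | None = None,
    clamps: Mapping[str, float] | ClampSet | None = None,
    eig_tol: float = EIG_TOL,
) -> Stability:
    """Label a fixed point by the eigenvalues of the frozen-eta x-Jacobian.

    Stable: every real part < -eig_tol.  Degenerate: some real part within
    eig_tol of zero.  Unstable otherwise.  Clamped nodes are excluded, so
    the Jacobian dimension equals the number of free nodes.
    """
    params = params or DynamicsParams()
    comp = CompiledDynamics(spec, params, clamps)
    x = attractor.x if isinstance(attractor, (Attractor, SystemState)) else np.asarray(attractor)
    eta = attractor.eta
    J = comp.x_jacobian(np.asarray(x, float), np.asarray(eta, float))
    if J.size == 0:
        return "stable"
    if not np.all(np.isfinite(J)):
        raise ValueError("non-finite Jacobian entries")
    ev = eigvals(J)
    re = ev.real
    if isinstance(attractor, Attractor):
        attractor.eigenvalues = ev
    if np.any(np.abs(re) <= eig_tol):
        return "degenerate"
    if np.all(re < -eig_tol):
        return "stable"
    return "unstable"


def find_attractors(
    spec: NetworkSpec,
    params: DynamicsParams | None = None,
    clamps: Mapping[str, float] | ClampSet | None = None,
    n_samples: int = 200,
    seed: int | None = 0,
    dedup_tol: float = DEDUP_TOL,
    initials: list[SystemState] | None = None,
) -> AttractorEnsemble:
    """Sample, integrate, deduplicate and classify the attractor set.

    Identity of an attractor is its concentration profile: two converged
    endpoints merge when their x-vectors differ by less than ``dedup_tol``
    in max-norm (degradation rates may differ between merged trajectories;
    their mean is stored).  Oscillatory trajectories are tallied separately
    and their trailing-window mean profiles deduplicated the same way, for
    functional-module reporting.
    """
    params = params or DynamicsParams()
    cs = clamps if isinstance(clamps, ClampSet) else ClampSet(clamps, spec)
    comp = CompiledDynamics(spec, params, cs)
    if initials is None:
        initials = sample_initials(n_samples, spec, params, seed=seed, clamps=cs)
    else:
        n_samples = len(initials)

    fixed: list[Attractor] = []
    fixed_eta_sums: list[np.ndarray] = []
    osc: list[Attractor] = []
    n_conv = n_osc = n_unres = 0
    for state0 in initials:
        out = integrate_to_steady(state0, spec, params, cs, dynamics=comp)
        if out.status == "converged":
            n_conv += 1
            hit = _match(fixed, out.state.x, dedup_tol)
            if hit is None:
                fixed.append(
                    Attractor(
                        x=out.state.x.copy(),
                        eta=out.state.eta.copy(),
                        stability="stable",
                        basin_count=1,
                        residual=out.residual,
                    )
                )
                fixed_eta_sums.append(out.state.eta.copy())
            else:
                fixed[hit].basin_count += 1
                fixed_eta_sums[hit] += out.state.eta
        elif out.status == "oscillatory":
            n_osc += 1
            hit = _match(osc, out.state.x, dedup_tol)
            if hit is None:
                osc.append(
                    Attractor(
                        x=out.state.x.copy(),
                        eta=out.state.eta.copy(),
                        stability="degenerate",
                        basin_count=1,
                        oscillatory=True,
                        node_oscillating=out.node_oscillating,
                    )
                )
            else:
                osc[hit].basin_count += 1
        else:
            n_unres += 1

    for a, esum in zip(fixed, fixed_eta_sums):
        a.eta = esum / a.basin_count
        if a.basin_count > 1:
            # averaging eta moves the point off the fixed-point manifold;
            # re-polish x at the stored eta so the residual invariant holds
            from .dynamics import _polish_fixed_point

            y = np.concatenate([a.x, a.eta])
            polished = _polish_fixed_point(comp, y)
            if polished is not None:
                a.x = comp.clamps.apply(polished[: spec.n_nodes])
        a.residual = comp.residual(np.concatenate([a.x, a.eta]))
        a.stability = classify_stability(a, spec, params, cs)

    if n_conv == 0:
        logger.warning("no trajectory converged (%d oscillatory, %d unresolved)", n_osc, n_unres)

    return AttractorEnsemble(
        spec=spec,
        attractors=fixed,
        oscillatory_profiles=osc,
        n_samples=n_samples,
        n_converged=n_conv,
        n_oscillatory=n_osc,
        n_unresolved=n_unres,
        seed=seed,
        dedup_tol=dedup_tol,
        clamps=dict(cs.items()),
    )


def _match(pool: list[Attractor], x: np.ndarray, tol: float) -> int | None:
    for i, a in enumerate(pool):
        if np.max(np.abs(a.x - x)) < tol:
            return i
    return None
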