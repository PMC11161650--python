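"""Hill-function network dynamics with a self-tuning degradation layer.

Each agent ``x_i`` (a concentration or pathway activity, dimensionless and
nonnegative) evolves as production minus first-order decay::

    dx_i/dt = g_i(x) - eta_i * x_i

where the production rate is a saturating Hill law combining all activators
(index set U_i) and inhibitors (V_i) of node ``i``::

    g_i(x) = [ sum_{u in U_i} a x_u^n / (1 + sum_{u in U_i} a x_u^n) ]
             * [ 1 / (1 + sum_{v in V_i} a x_v^n) ]

with Hill coefficient ``n = 3`` and affinity weight ``a = 10`` by default.
``g_i`` lies in ``[0, 1)``; a node with no activators has zero production.

The degradation rate ``eta_i = 1/tau_i`` is itself dynamic::

    deta_i/dt = kappa * [ (dx_i/dt)^2 + 2 (dx_i/dt) eta_i x_i ]
              = kappa * [ g_i(x)^2 - (eta_i x_i)^2 ]

with ``kappa = 3/2``.  The two forms are algebraically identical; the second
makes the behaviour transparent: eta_i relaxes toward ``g_i(x)/x_i``, i.e.
the degradation time of every agent self-adjusts until production and decay
balance, which stabilizes the reachable steady states.  The layer freezes
(deta/dt = 0) exactly at fixed points of x.  Because the right-hand side can
drive eta negative during downward transients, eta is floored at a small
positive value (``eta_floor``); negative degradation is unphysical.

Clamping a node (an in-silico intervention: 0 = full inhibition, 1 = full
activation) pins both its concentration and its degradation rate: both
derivatives are exactly zero for clamped nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .netspec import NetworkSpec

logger = logging.getLogger(__name__)

Outcome = Literal["converged", "oscillatory", "unresolved"]


@dataclass(frozen=True)
class DynamicsParams:
    """Tunable constants of the dynamics and of steady-state detection.

    Attributes
    ----------
    hill_n : float
        Hill coefficient (cooperativity), default 3.
    hill_a : float
        Affinity weight, the reciprocal apparent dissociation constant,
        default 10.
    kappa : float
        Scale of the degradation-regulation layer, default 3/2.
    eta_floor : float
        Hard lower bound on degradation rates (clipped), default 1e-3.
    eta_dynamics : bool
        If False the degradation layer is disabled and ``eta`` is held at
        ``eta_fixed`` for every node; the system then reduces to the
        classical fixed-degradation endogenous-network form.
    eta_fixed : float
        Degradation rate used when ``eta_dynamics`` is off.
    t_max : float
        Integration horizon in model time units.
    steady_tol : float
        Residual threshold: a trajectory has converged when the max-norm of
        dx/dt over free nodes stays below this for a full ``window``.
    window : float
        Trailing time span over which convergence/oscillation is judged.
    x_init, eta_init : tuple
        Uniform sampling ranges for random initial conditions.
    polish : bool
        Newton-polish nearly-converged states onto the exact fixed point
        (eta frozen); accelerates termination and sharpens deduplication.
    x_bound : float
        States above this are treated as divergent (unresolved).
    """

    hill_n: float = 3.0
    hill_a: float = 10.0
    kappa: float = 1.5
    eta_floor: float = 1e-3
    eta_dynamics: bool = True
    eta_fixed: float = 1.0
    t_max: float = 500.0
    steady_tol: float = 1e-8
    window: float = 10.0
    x_init: tuple[float, float] = (0.0, 1.0)
    eta_init: tuple[float, float] = (0.5, 1.5)
    polish: bool = True
    x_bound: float = 100.0

    def __post_init__(self) -> None:
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if self.hill_a <= 0:
            raise ValueError("hill_a must be > 0")
        if self.eta_floor <= 0:
            raise ValueError("eta_floor must be > 0")
        if self.steady_tol <= 0:
            raise ValueError("steady_tol must be > 0")
        if self.window <= 0 or self.t_max <= self.window:
            raise ValueError("need 0 < window < t_max")

    def with_(self, **kw) -> "DynamicsParams":
        return replace(self, **kw)


@dataclass
class SystemState:
    """Concentration vector ``x`` and degradation-rate vector ``eta``."""

    x: np.ndarray
    eta: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.x.shape != self.eta.shape or self.x.ndim != 1:
            raise ValueError("x and eta must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.eta))):
            raise ValueError("state contains non-finite entries")

    @property
    def n(self) -> int:
        return self.x.size

    def copy(self) -> "SystemState":
        return SystemState(self.x.copy(), self.eta.copy())


class ClampSet:
    """Mapping node -> held value, the in-silico intervention primitive."""

    def __init__(
        self,
        clamps: Mapping[str, float] | None,
        spec: NetworkSpec,
        binary_only: bool = False,
    ) -> None:
        clamps = dict(clamps or {})
        for node, val in clamps.items():
            spec.index(node)  # raises on unknown node
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"clamp value for {node!r} must be finite and >= 0")
            if binary_only and val not in (0.0, 1.0):
                raise ValueError(f"clamp value for {node!r} must be 0 or 1")
        self._clamps = clamps
        self._spec = spec

    def __len__(self) -> int:
        return len(self._clamps)

    def items(self):
        return self._clamps.items()

    def indices(self) -> np.ndarray:
        return np.array([self._spec.index(n) for n in self._clamps], dtype=int)

    def values(self) -> np.ndarray:
        return np.array(list(self._clamps.values()), dtype=float)

    def free_mask(self) -> np.ndarray:
        mask = np.ones(self._spec.n_nodes, dtype=bool)
        if self._clamps:
            mask[self.indices()] = False
        return mask

    def apply(self, x: np.ndarray) -> np.ndarray:
        out = np.array(x, dtype=float, copy=True)
        if self._clamps:
            out[self.indices()] = self.values()
        return out


class CompiledDynamics:
    """Vectorized right-hand side, production law and Jacobians.

    Compiling once per (network, params, clamps) avoids re-deriving the
    adjacency structure inside the integrator loop.
    """

    def __init__(
        self,
        spec: NetworkSpec,
        params: DynamicsParams,
        clamps: ClampSet | Mapping[str, float] | None = None,
    ) -> None:
        self.spec = spec
        self.params = params
        self.clamps = clamps if isinstance(clamps, ClampSet) else ClampSet(clamps, spec)
        act, inh = spec.adjacency()
        self.act = act.astype(float)
        self.inh = inh.astype(float)
        self.free = self.clamps.free_mask()
        self.n = spec.n_nodes

    # -- production law --------------------------------------------------

    def production(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        xn = np.maximum(x, 0.0) ** p.hill_n
        A = p.hill_a * (self.act @ xn)
        B = p.hill_a * (self.inh @ xn)
        return (A / (1.0 + A)) * (1.0 / (1.0 + B))

    def production_jac(self, x: np.ndarray) -> np.ndarray:
        """dg_i/dx_j, analytic."""
        p = self.params
        xs = np.maximum(x, 0.0)
        xn = xs**p.hill_n
        dxn = p.hill_n * xs ** (p.hill_n - 1.0)
        A = p.hill_a * (self.act @ xn)
        B = p.hill_a * (self.inh @ xn)
        actf = A / (1.0 + A)
        inhf = 1.0 / (1.0 + B)
        # d actf / dA = 1/(1+A)^2 ; d inhf / dB = -1/(1+B)^2
        dA = self.act * (p.hill_a * dxn)[None, :]
        dB = self.inh * (p.hill_a * dxn)[None, :]
        return (inhf / (1.0 + A) ** 2)[:, None] * dA - (actf / (1.0 + B) ** 2)[:, None] * dB

    # -- joint (x, eta) system -------------------------------------------

    def _eta_eff(self, eta: np.ndarray) -> np.ndarray:
        p = self.params
        if not p.eta_dynamics:
            return np.full_like(eta, p.eta_fixed)
        return np.maximum(eta, p.eta_floor)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.params
        x, eta = y[: self.n], y[self.n :]
        eta_eff = self._eta_eff(eta)
        g = self.production(x)
        dx = g - eta_eff * x
        dx[~self.free] = 0.0
        if p.eta_dynamics:
            deta = p.kappa * dx * (dx + 2.0 * eta_eff * x)
            # at the floor, never push eta further down
            deta = np.where((eta <= p.eta_floor) & (deta < 0.0), 0.0, deta)
        else:
            deta = np.zeros_like(eta)
        deta[~self.free] = 0.0
        return np.concatenate([dx, deta])

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.params
        n = self.n
        x, eta = y[:n], y[n:]
        eta_eff = self._eta_eff(eta)
        g = self.production(x)
        dgdx = self.production_jac(x)
        J = np.zeros((2 * n, 2 * n))
        Jxx = dgdx - np.diag(eta_eff)
        J[:n, :n] = Jxx
        if p.eta_dynamics:
            J[:n, n:] = -np.diag(x)
            # deta/dt = kappa*(g^2 - eta^2 x^2)
            J[n:, :n] = p.kappa * (2.0 * g[:, None] * dgdx - np.diag(2.0 * eta_eff**2 * x))
            J[n:, n:] = -np.diag(2.0 * p.kappa * eta_eff * x**2)
        clamped = ~self.free
        J[:n][clamped, :] = 0.0
        J[n:][clamped, :] = 0.0
        return J

    def x_jacobian(self, x: np.ndarray, eta: np.ndarray) -> np.ndarray:
        """Jacobian of the x-subsystem at frozen eta, free nodes only."""
        eta_eff = self._eta_eff(eta)
        Jxx = self.production_jac(x) - np.diag(eta_eff)
        return Jxx[np.ix_(self.free, self.free)]

    def pack(self, state: SystemState) -> np.ndarray:
        x = self.clamps.apply(state.x)
        eta = state.eta if self.params.eta_dynamics else np.full(self.n, self.params.eta_fixed)
        return np.concatenate([x, np.maximum(eta, self.params.eta_floor)])

    def unpack(self, y: np.ndarray) -> SystemState:
        x = self.clamps.apply(y[: self.n])
        eta = self._eta_eff(y[self.n :])
        return SystemState(x, eta)

    def residual(self, y: np.ndarray) -> float:
        """Max-norm of dx/dt over free nodes (the convergence criterion)."""
        dx = self.rhs(0.0, y)[: self.n]
        if not self.free.any():
            return 0.0
        return float(np.max(np.abs(dx[self.free])))


# -- spec-level operations (scalar/typed surface) --------------------------


def production_rate(
    x: np.ndarray | Mapping[str, float],
    target: str,
    spec: NetworkSpec,
    params: DynamicsParams | None = None,
) -> float:
    """Hill production rate of ``target`` given node levels ``x``; in [0, 1)."""
    params = params or DynamicsParams()
    if isinstance(x, Mapping):
        vec = np.zeros(spec.n_nodes)
        for node, val in x.items():
            vec[spec.index(node)] = val
    else:
        vec = np.asarray(x, dtype=float)
    i = spec.index(target)
    return float(CompiledDynamics(spec, params).production(vec)[i])


def eta_rhs(dxdt_i: float, eta_i: float, x_i: float, params: DynamicsParams | None = None) -> float:
    """Rate of change of one degradation parameter given dx/dt, eta, x."""
    params = params or DynamicsParams()
    return params.kappa * (dxdt_i**2 + 2.0 * dxdt_i * eta_i * x_i)


def rhs(
    state: SystemState,
    spec: NetworkSpec,
    params: DynamicsParams | None = None,
    clamps: Mapping[str, float] | ClampSet | None = None,
) -> SystemState:
    """Time derivative of the joint state (dx/dt, deta/dt)."""
    params = params or DynamicsParams()
    comp = CompiledDynamics(spec, params, clamps)
    dy = comp.rhs(0.0, comp.pack(state))
    return SystemState(dy[: spec.n_nodes], dy[spec.n_nodes :])


@dataclass
class TrajectoryOutcome:
    """Result of integrating one initial condition to its asymptotic fate."""

    status: Outcome
    state: SystemState
    t_end: float
    residual: float
    amplitude: np.ndarray | None = None  # per-node max-min over last window
    diagnostic: str = ""
    eta_clipped: bool = False

    @property
    def node_oscillating(self) -> np.ndarray | None:
        if self.amplitude is None:
            return None
        return self.amplitude > 0.05  # meaningful swing on the [0, 1) scale


def integrate_to_steady(
    state0: SystemState,
    spec: NetworkSpec,
    params: DynamicsParams | None = None,
    clamps: Mapping[str, float] | ClampSet | None = None,
    dynamics: CompiledDynamics | None = None,
) -> TrajectoryOutcome:
    """Integrate until the state converges, oscillates, or the horizon ends.

    Convergence requires the free-node residual ``max_i |dx_i/dt|`` to stay
    below ``steady_tol`` across the trailing ``window``.  When ``polish`` is
    on, a nearly-converged state (residual < 1e-5) is refined by a damped
    Newton solve of ``g(x) = eta x`` at frozen eta; the polished point is a
    genuine fixed point of the joint system since deta/dt vanishes with
    dx/dt.  A bounded non-converged trajectory whose trailing amplitude
    exceeds ``steady_tol`` is flagged oscillatory; anything else (divergence,
    non-finite values, integrator failure) is unresolved.
    """
    params = params or DynamicsParams()
    comp = dynamics if dynamics is not None else CompiledDynamics(spec, params, clamps)
    y = comp.pack(state0)
    n = comp.n
    t = 0.0
    chunk = max(4.0 * params.window, 20.0)
    eta_clipped = False
    polish_tried_at = -np.inf

    while t < params.t_max:
        t_next = min(t + chunk, params.t_max)
        try:
            sol = solve_ivp(
                comp.rhs,
                (t, t_next),
                y,
                method="LSODA",
                jac=comp.jac,
                rtol=1e-8,
                atol=1e-10,
                dense_output=True,
            )
        except Exception as exc:  # pragma: no cover - integrator blow-up
            return TrajectoryOutcome(
                "unresolved", comp.unpack(y), t, np.inf, diagnostic=f"integrator error: {exc}"
            )
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            return TrajectoryOutcome(
                "unresolved",
                comp.unpack(y),
                t,
                np.inf,
                diagnostic=f"integration failed: {sol.message}",
            )
        y = sol.y[:, -1]
        if params.eta_dynamics and np.any(sol.y[n:, :] < params.eta_floor - 1e-12):
            eta_clipped = True
            logger.debug("eta clipped at floor %.1e", params.eta_floor)
            y[n:] = np.maximum(y[n:], params.eta_floor)
        t = t_next

        # convergence: residual below tol across the trailing window
        ts = np.linspace(max(sol.t[0], t - params.window), t, 6)
        res = max(comp.residual(sol.sol(ti)) for ti in ts)
        if res < params.steady_tol:
            return TrajectoryOutcome(
                "converged", comp.unpack(y), t, res, eta_clipped=eta_clipped
            )

        # near-converged: polish onto the exact fixed point
        if params.polish and res < 1e-5 and t - polish_tried_at >= chunk:
            polish_tried_at = t
            polished = _polish_fixed_point(comp, y)
            if polished is not None:
                return TrajectoryOutcome(
                    "converged",
                    comp.unpack(polished),
                    t,
                    comp.residual(polished),
                    eta_clipped=eta_clipped,
                )

        if np.max(np.abs(y[:n])) > params.x_bound:
            return TrajectoryOutcome(
                "unresolved", comp.unpack(y), t, res, diagnostic="state diverged"
            )

    # horizon reached: oscillatory vs unresolved, judged on trailing window
    ts = np.linspace(t - params.window, t, 25)
    traj = np.stack([sol.sol(ti)[:n] for ti in ts], axis=1)
    amplitude = traj.max(axis=1) - traj.min(axis=1)
    res = comp.residual(y)
    bounded = np.max(np.abs(traj)) <= params.x_bound
    if bounded and np.max(amplitude[comp.free]) > params.steady_tol:
        return TrajectoryOutcome(
            "oscillatory", comp.unpack(y), t, res, amplitude=amplitude, eta_clipped=eta_clipped
        )
    return TrajectoryOutcome(
        "unresolved",
        comp.unpack(y),
        t,
        res,
        amplitude=amplitude,
        diagnostic="no convergence within t_max",
        eta_clipped=eta_clipped,
    )


def _polish_fixed_point(comp: CompiledDynamics, y: np.ndarray) -> np.ndarray | None:
    """Newton-refine x at frozen eta; accept only a nearby, exact root."""
    n = comp.n
    params = comp.params
    x0, eta = y[:n].copy(), y[n:]
    eta_eff = comp._eta_eff(eta)
    free = comp.free

    def fun(xf: np.ndarray) -> np.ndarray:
        x = x0.copy()
        x[free] = xf
        return (comp.production(x) - eta_eff * x)[free]

    def jac(xf: np.ndarray) -> np.ndarray:
        x = x0.copy()
        x[free] = xf
        return (comp.production_jac(x) - np.diag(eta_eff))[np.ix_(free, free)]

    try:
        sol = root(fun, x0[free], jac=jac, method="hybr", tol=1e-13)
    except Exception:  # pragma: no cover
        return None
    if not sol.success:
        return None
    step = np.max(np.abs(sol.x - x0[free])) if free.any() else 0.0
    if step > 0.05 or np.any(sol.x < -1e-9):
        return None
    out = y.copy()
    out[:n][free] = np.maximum(sol.x, 0.0)
    if comp.residual(out) >= params.steady_tol:
        return None
    return out
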