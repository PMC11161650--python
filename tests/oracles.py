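"""Independent brute-force oracles used by the tests.

Everything here is deliberately separate from the package's integration
machinery: a direct transcription of the Hill production law, a fixed-step
RK4 integrator, grid-based basin enumeration and finite-difference
Jacobian stability, all plain numpy.  Slower and simpler than the library
path, by design.
"""

from __future__ import annotations

import itertools

import numpy as np


def hill_g(x: np.ndarray, act_sets, inh_sets, n=3.0, a=10.0) -> np.ndarray:
    """Direct per-node transcription of the Hill production law."""
    g = np.empty(len(x))
    for i in range(len(x)):
        A = sum(a * x[u] ** n for u in act_sets[i])
        B = sum(a * x[v] ** n for v in inh_sets[i])
        g[i] = (A / (1.0 + A)) * (1.0 / (1.0 + B))
    return g


def rhs_fixed_eta(x: np.ndarray, act_sets, inh_sets, eta=1.0, n=3.0, a=10.0) -> np.ndarray:
    return hill_g(np.maximum(x, 0.0), act_sets, inh_sets, n=n, a=a) - eta * x


def _sets_to_masks(act_sets, inh_sets):
    m = len(act_sets)
    act = np.zeros((m, m))
    inh = np.zeros((m, m))
    for i in range(m):
        for u in act_sets[i]:
            act[i, u] = 1.0
        for v in inh_sets[i]:
            inh[i, v] = 1.0
    return act, inh


def rk4_integrate(x0, act_sets, inh_sets, eta=1.0, t_end=300.0, dt=0.02, n=3.0, a=10.0):
    """Fixed-step RK4; returns the final state (batched over rows of x0).

    The same Hill formula as :func:`hill_g`, written in batched matrix form
    so a whole grid of initial conditions advances in lock-step.
    """
    x = np.atleast_2d(np.asarray(x0, dtype=float)).copy()
    act, inh = _sets_to_masks(act_sets, inh_sets)

    def f(xb):
        xn = np.maximum(xb, 0.0) ** n
        A = a * (xn @ act.T)
        B = a * (xn @ inh.T)
        return (A / (1.0 + A)) * (1.0 / (1.0 + B)) - eta * xb

    steps = int(round(t_end / dt))
    for _ in range(steps):
        k1 = f(x)
        k2 = f(x + 0.5 * dt * k1)
        k3 = f(x + 0.5 * dt * k2)
        k4 = f(x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return x


def spec_to_sets(spec):
    """Activator/inhibitor index sets of a NetworkSpec (structure only)."""
    acts = [[spec.index(s) for s in spec.activators(t)] for t in spec.nodes]
    inhs = [[spec.index(s) for s in spec.inhibitors(t)] for t in spec.nodes]
    return acts, inhs


def numeric_jacobian(x, act_sets, inh_sets, eta=1.0, h=1e-6, n=3.0, a=10.0):
    m = len(x)
    J = np.empty((m, m))
    for j in range(m):
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (
            rhs_fixed_eta(xp, act_sets, inh_sets, eta, n, a)
            - rhs_fixed_eta(xm, act_sets, inh_sets, eta, n, a)
        ) / (2 * h)
    return J


def grid_attractors(
    spec,
    eta=1.0,
    grid=7,
    box=(0.0, 1.0),
    t_end=300.0,
    dt=0.02,
    dedup_tol=1e-3,
    res_tol=1e-8,
):
    """Exhaustive grid integration: unique converged endpoints + stability.

    Returns (attractors, n_unconverged) where each attractor is a dict
    with keys x, stability, basin (grid-point tally).
    """
    acts, inhs = spec_to_sets(spec)
    m = spec.n_nodes
    pts = np.linspace(box[0], box[1], grid)
    x0 = np.array(list(itertools.product(pts, repeat=m)))
    final = rk4_integrate(x0, acts, inhs, eta=eta, t_end=t_end, dt=dt)
    found = []
    n_unconv = 0
    for xf in final:
        res = np.max(np.abs(rhs_fixed_eta(xf, acts, inhs, eta=eta)))
        if res >= res_tol:
            n_unconv += 1
            continue
        for rec in found:
            if np.max(np.abs(rec["x"] - xf)) < dedup_tol:
                rec["basin"] += 1
                break
        else:
            J = numeric_jacobian(xf, acts, inhs, eta=eta)
            re = np.linalg.eigvals(J).real
            if np.all(re < -1e-6):
                stab = "stable"
            elif np.any(np.abs(re) <= 1e-6):
                stab = "degenerate"
            else:
                stab = "unstable"
            found.append({"x": xf.copy(), "stability": stab, "basin": 1})
    return found, n_unconv


def enumerate_two_node_networks():
    """All 2-node signed patterns: 9 cross-edge combos x 2 self-loop modes.

    Cross edges A->B and B->A each in {absent, +, -}; self-loops either
    absent on both nodes or activating on both.  The all-absent pattern is
    skipped (a network needs at least one edge).  Yields edge lists.
    """
    options = (None, 1, -1)
    for ab, ba in itertools.product(options, repeat=2):
        for self_act in (False, True):
            edges = []
            if self_act:
                edges += [("A", "A", 1), ("B", "B", 1)]
            if ab is not None:
                edges.append(("A", "B", ab))
            if ba is not None:
                edges.append(("B", "A", ba))
            if edges:
                yield edges
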