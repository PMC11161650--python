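"""Signed interaction networks.

A :class:`NetworkSpec` is the static description of an endogenous network:
an ordered list of molecular/cellular agents (nodes) and a list of signed
directed edges, ``+1`` for activation and ``-1`` for inhibition.  The
per-target activator and inhibitor index sets derived from it parameterize
the Hill production law in :mod:`endonet.dynamics`.

The on-disk format is a tab-separated table with header
``source<TAB>target<TAB>sign``; sign tokens ``+1/1/+/activate`` and
``-1/−/-/inhibit`` are accepted.  Tab separation is deliberate: molecule
names such as ``CyclinE/Cdk2`` contain punctuation that would collide with
comma- or slash-delimited formats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_POS_TOKENS = {"+1", "1", "+", "activate", "activation", "promote"}
_NEG_TOKENS = {"-1", "−1", "-", "−", "inhibit", "inhibition", "repress"}


class NetworkParseError(ValueError):
    """Raised when an interaction table cannot be parsed."""


@dataclass(frozen=True)
class NetworkSpec:
    """Nodes plus signed directed edges of an endogenous network.

    Parameters
    ----------
    nodes
        Unique node identifiers in a fixed order; this order defines the
        index space used by every downstream state vector.
    edges
        ``(source, target, sign)`` triples with ``sign`` in ``{+1, -1}``.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, int], ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            dupes = sorted({n for n in self.nodes if list(self.nodes).count(n) > 1})
            raise ValueError(f"duplicate node identifiers: {dupes}")
        index = {name: i for i, name in enumerate(self.nodes)}
        for src, tgt, sign in self.edges:
            if src not in index or tgt not in index:
                raise ValueError(f"edge ({src!r}, {tgt!r}) references undeclared node")
            if sign not in (1, -1):
                raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
        object.__setattr__(self, "_index", index)

    # -- basic queries ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def activators(self, target: str) -> list[str]:
        """Nodes with an activating edge onto ``target``."""
        self.index(target)
        return [s for s, t, w in self.edges if t == target and w == 1]

    def inhibitors(self, target: str) -> list[str]:
        """Nodes with an inhibiting edge onto ``target``."""
        self.index(target)
        return [s for s, t, w in self.edges if t == target and w == -1]

    def adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (activation, inhibition) matrices, ``M[i, u]`` = u -> i."""
        n = self.n_nodes
        act = np.zeros((n, n), dtype=bool)
        inh = np.zeros((n, n), dtype=bool)
        for src, tgt, sign in self.edges:
            i, u = self._index[tgt], self._index[src]
            (act if sign == 1 else inh)[i, u] = True
        return act, inh


def _parse_sign(token: str, lineno: int) -> int:
    t = token.strip().lower()
    if t in _POS_TOKENS:
        return 1
    if t in _NEG_TOKENS:
        return -1
    raise NetworkParseError(f"line {lineno}: unknown sign token {token!r}")


def network_from_edges(
    edges: Iterable[tuple[str, str, int]],
    nodes: Sequence[str] | None = None,
    allow_conflicts: bool = False,
) -> NetworkSpec:
    """Build a :class:`NetworkSpec` from edge triples.

    Node order is first appearance (source before target, row by row) unless
    an explicit ``nodes`` sequence is given.  Identical duplicate edges are
    collapsed silently (with a log note); duplicates with conflicting signs
    raise unless ``allow_conflicts`` is set, in which case both are kept and
    the node acts as both activator and inhibitor of the target.
    """
    seen_nodes: dict[str, None] = {}
    kept: list[tuple[str, str, int]] = []
    signs_by_pair: dict[tuple[str, str], set[int]] = {}
    for src, tgt, sign in edges:
        src, tgt = src.strip(), tgt.strip()
        seen_nodes.setdefault(src)
        seen_nodes.setdefault(tgt)
        pair = (src, tgt)
        prev = signs_by_pair.setdefault(pair, set())
        if sign in prev:
            logger.info("collapsing duplicate edge %s -> %s (%+d)", src, tgt, sign)
            continue
        if prev and not allow_conflicts:
            raise NetworkParseError(
                f"conflicting signs for edge {src} -> {tgt}; "
                "pass allow_conflicts=True to keep both"
            )
        prev.add(sign)
        kept.append((src, tgt, sign))
    if not kept:
        raise NetworkParseError("no edges")
    node_order = tuple(nodes) if nodes is not None else tuple(seen_nodes)
    return NetworkSpec(nodes=node_order, edges=tuple(kept))


def parse_network(path: str | Path, allow_conflicts: bool = False) -> NetworkSpec:
    """Read a signed interaction table (TSV) into a :class:`NetworkSpec`."""
    path = Path(path)
    rows: list[tuple[str, str, int]] = []
    declared: list[str] | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.lstrip().startswith("#nodes:"):
                declared = [n for n in line.split(":", 1)[1].split("\t") if n.strip()]
                declared = [n.strip() for n in declared]
                continue
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if not rows and [p.lower() for p in parts[:3]] == ["source", "target", "sign"]:
                continue
            if len(parts) < 3:
                raise NetworkParseError(
                    f"line {lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            src, tgt, token = parts[0], parts[1], parts[2]
            if not src or not tgt:
                raise NetworkParseError(f"line {lineno}: empty node name")
            rows.append((src, tgt, _parse_sign(token, lineno)))
    if not rows:
        raise NetworkParseError(f"{path}: no edges")
    return network_from_edges(rows, nodes=declared, allow_conflicts=allow_conflicts)


def write_network(spec: NetworkSpec, path: str | Path) -> Path:
    """Write ``spec`` as a TSV interaction table (round-trips via parse)."""
    path = Path(path)
    with path.open("w") as fh:
        # node-order directive keeps round-trips exact (edge rows alone
        # cannot encode isolated nodes or a non-first-appearance order)
        fh.write("#nodes:" + "\t".join(spec.nodes) + "\n")
        fh.write("source\ttarget\tsign\n")
        for src, tgt, sign in spec.edges:
            fh.write(f"{src}\t{tgt}\t{sign:+d}\n")
    return path


@dataclass
class ValidationReport:
    """Report-only network diagnostics; never raises."""

    no_activator_nodes: list[str]
    isolated_nodes: list[str]
    self_loops: list[tuple[str, int]]

    @property
    def warnings(self) -> list[str]:
        out = [
            f"no activators: steady state 0 for node {n!r}" for n in self.no_activator_nodes
        ]
        out += [f"isolated node {n!r}" for n in self.isolated_nodes]
        return out

    @property
    def notes(self) -> list[str]:
        return [f"self-loop on {n!r} ({s:+d})" for n, s in self.self_loops]


def validate_network(spec: NetworkSpec) -> ValidationReport:
    """Diagnose structural features that shape the dynamics.

    A node without activators has zero production under the Hill law and is
    forced to the zero steady state; isolated nodes carry no information;
    self-loops are legitimate (auto-activation is the standard way to model
    constitutive or self-sustaining activity) and only reported.
    """
    touched = {s for s, _, _ in spec.edges} | {t for _, t, _ in spec.edges}
    no_act = [n for n in spec.nodes if n in touched and not spec.activators(n)]
    isolated = [n for n in spec.nodes if n not in touched]
    loops = [(s, w) for s, t, w in spec.edges if s == t]
    return ValidationReport(no_act, isolated, loops)
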