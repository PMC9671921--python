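"""Regular vine (R-vine) structures and copula models.

An R-vine on ``n`` variables arranges the n(n-1)/2 pair-copulas of a
pair-copula construction on a nested sequence of trees T_1..T_{n-1}: the
nodes of T_{i+1} are the edges of T_i, and two edges may be joined only if
they share a node (the proximity condition).  Every edge carries a conditioned
pair (a, b) and a conditioning set D; the copula density factorizes as the
product over all edges of c_{a,b|D} evaluated at conditional cdfs that are
themselves built recursively from h-functions of lower trees.

A model is *truncated* at level k when every edge in trees above k carries the
independence copula, and *pruned* when individual weak edges anywhere are set
to independence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bivariate import INDEPENDENCE, BivariateCopula, bicop_hfunc, bicop_hinv

__all__ = [
    "VineEdge",
    "RVineStructure",
    "RVineModel",
    "validate_structure",
    "rvine_logdensity",
    "rvine_sample",
    "truncate_model",
    "count_parameters",
    "StructureError",
]


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class VineEdge:
    """Structural edge: conditioned pair (a, b) given conditioning set."""

    a: int
    b: int
    conditioning: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "conditioning", frozenset(self.conditioning))
        if self.a == self.b or self.a in self.conditioning or self.b in self.conditioning:
            raise StructureError(f"degenerate edge ({self.a},{self.b}|{set(self.conditioning)})")

    @property
    def variables(self) -> frozenset:
        return self.conditioning | {self.a, self.b}

    @property
    def tree(self) -> int:
        return len(self.conditioning) + 1

    def key(self):
        return (frozenset((self.a, self.b)), self.conditioning)

    def __repr__(self):
        if self.conditioning:
            cond = ",".join(str(c) for c in sorted(self.conditioning))
            return f"({self.a},{self.b}|{cond})"
        return f"({self.a},{self.b})"


class RVineStructure:
    """Vine skeleton: a list of trees, each a list of :class:`VineEdge`.

    Variables are labelled 0..n-1 internally (serialized 1-based).
    """

    def __init__(self, n: int, trees: Sequence[Sequence[VineEdge]]):
        self.n = int(n)
        self.trees = [list(t) for t in trees]

    # -- convenience constructors ---------------------------------------
    @classmethod
    def dvine(cls, order: Sequence[int]) -> "RVineStructure":
        """Path-shaped vine: variables chained in the given order."""
        o = list(order)
        n = len(o)
        trees = []
        for t in range(1, n):
            tree = []
            for i in range(n - t):
                cond = frozenset(o[i + 1:i + t])
                tree.append(VineEdge(o[i], o[i + t], cond))
            trees.append(tree)
        return cls(n, trees)

    @classmethod
    def cvine(cls, order: Sequence[int]) -> "RVineStructure":
        """Star-shaped vine: order[t-1] is the root of tree t."""
        o = list(order)
        n = len(o)
        trees = []
        for t in range(1, n):
            root = o[t - 1]
            cond = frozenset(o[:t - 1])
            trees.append([VineEdge(root, x, cond) for x in o[t:]])
        return cls(n, trees)

    # -------------------------------------------------------------------
    def validate(self):
        """Check Definition-style conditions; raises StructureError."""
        report = validate_structure(self)
        if report != "ok":
            raise StructureError(report)

    def edge_count(self) -> int:
        return sum(len(t) for t in self.trees)

    def __repr__(self):
        return f"RVineStructure(n={self.n}, trees={[len(t) for t in self.trees]})"


def validate_structure(s: RVineStructure) -> str:
    """Return 'ok' or a description of the first violated vine condition."""
    n = s.n
    if len(s.trees) > n - 1:
        return f"too many trees: {len(s.trees)} for n={n}"
    for i, tree in enumerate(s.trees, start=1):
        if len(tree) != n - i:
            return f"tree {i} has {len(tree)} edges, expected {n - i}"
        for e in tree:
            if e.tree != i:
                return f"edge {e} has conditioning size {len(e.conditioning)} in tree {i}"
            if not e.variables <= set(range(n)):
                return f"edge {e} uses variables outside 0..{n - 1}"
    # tree 1 must be a spanning tree on the variables
    if s.trees:
        import networkx as nx

        g = nx.Graph((e.a, e.b) for e in s.trees[0])
        if g.number_of_nodes() != n or not nx.is_connected(g):
            return "tree 1 is not a spanning tree on all variables"
    # node inheritance + proximity: every edge of tree i+1 must join two
    # tree-i edges sharing i-1 variables, with conditioning = intersection
    for i in range(1, len(s.trees)):
        prev = s.trees[i - 1]
        for e in s.trees[i]:
            parents = [
                (p, q) for pi, p in enumerate(prev) for q in prev[pi + 1:]
                if p.variables | q.variables == e.variables
                and p.variables & q.variables == e.conditioning
            ]
            if not parents:
                return (f"proximity violation: edge {e} of tree {i + 1} does not join "
                        f"two adjacent tree-{i} edges")
    return "ok"


# ----------------------------------------------------------------------
# model = structure + copulas (+ truncation level)
# ----------------------------------------------------------------------

class RVineModel:
    """An R-vine copula model: structure, per-edge pair-copulas, truncation.

    ``copulas`` is a list parallel to ``structure.trees``; trees beyond
    ``truncation_level`` are treated as (and normalized to) independence.
    """

    def __init__(self, structure: RVineStructure,
                 copulas: Sequence[Sequence[BivariateCopula]],
                 truncation_level: int | None = None):
        self.structure = structure
        self.copulas = [list(c) for c in copulas]
        if len(self.copulas) != len(structure.trees):
            raise StructureError("copula list does not match structure trees")
        for tree, cops in zip(structure.trees, self.copulas):
            if len(tree) != len(cops):
                raise StructureError("copula count does not match edge count in a tree")
        if truncation_level is None:
            truncation_level = self._effective_level()
        if not (0 <= truncation_level <= structure.n - 1):
            raise StructureError(f"truncation level {truncation_level} out of [0, {structure.n - 1}]")
        self.truncation_level = int(truncation_level)
        # normalize: everything beyond the truncation level is independence
        for t in range(self.truncation_level, len(self.copulas)):
            self.copulas[t] = [INDEPENDENCE] * len(self.copulas[t])

    def _effective_level(self) -> int:
        level = 0
        for t, cops in enumerate(self.copulas, start=1):
            if any(c.family != "independence" for c in cops):
                level = t
        return level

    @property
    def n(self) -> int:
        return self.structure.n

    def edges(self):
        """Yield (edge, copula) over all trees in order."""
        for tree, cops in zip(self.structure.trees, self.copulas):
            yield from zip(tree, cops)

    def n_copula_params(self) -> int:
        return sum(c.n_params for _, c in self.edges())

    def nonindependence_counts(self) -> list:
        """q_i: number of non-independence pair-copulas per tree, padded to n-1."""
        q = [sum(1 for c in cops if c.family != "independence") for cops in self.copulas]
        return q + [0] * (self.n - 1 - len(q))

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        # matrix encoding needs all n-1 trees; pad a truncated structure
        # with independence trees for the serialization only
        full = self if len(self.structure.trees) == self.n - 1 else _complete_structure(self)
        order, _ = _peel_columns(full.structure)
        return {
            "n": self.n,
            "truncation_level": self.truncation_level,
            "order": [v + 1 for v in order],
            "structure_matrix": structure_matrix(full.structure).tolist(),
            "trees": [
                [
                    {
                        "conditioned": [e.a + 1, e.b + 1],
                        "conditioning": sorted(v + 1 for v in e.conditioning),
                        **c.to_dict(),
                    }
                    for e, c in zip(tree, cops)
                ]
                for tree, cops in zip(self.structure.trees, self.copulas)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RVineModel":
        n = int(d["n"])
        trees, cops = [], []
        for tree in d["trees"]:
            tedges, tcops = [], []
            for rec in tree:
                a, b = rec["conditioned"]
                cond = frozenset(v - 1 for v in rec["conditioning"])
                tedges.append(VineEdge(a - 1, b - 1, cond))
                tcops.append(BivariateCopula.from_dict(rec))
            trees.append(tedges)
            cops.append(tcops)
        return cls(RVineStructure(n, trees), cops, d.get("truncation_level"))

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RVineModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __repr__(self):
        return (f"RVineModel(n={self.n}, trunc={self.truncation_level}, "
                f"params={self.n_copula_params()})")


# ----------------------------------------------------------------------
# density
# ----------------------------------------------------------------------

def rvine_logdensity(m: RVineModel, U) -> np.ndarray:
    """Per-row log copula density of the vine (the copula factor only).

    ``U`` is a (T, n) array of pseudo-observations in (0,1).  Conditional
    arguments are built tree-by-tree with h-functions; trees beyond the
    truncation level contribute nothing.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if U.shape[1] != m.n:
        raise ValueError(f"U has {U.shape[1]} columns, model expects {m.n}")
    pseudo = {(j, frozenset()): U[:, j] for j in range(m.n)}
    out = np.zeros(U.shape[0])
    last_tree = min(m.truncation_level, len(m.structure.trees))
    for t in range(last_tree):
        is_last = t == last_tree - 1
        for e, cop in zip(m.structure.trees[t], m.copulas[t]):
            u1 = pseudo[(e.a, e.conditioning)]
            u2 = pseudo[(e.b, e.conditioning)]
            if cop.family != "independence":
                ll = cop.logpdf(u1, u2)
                if not np.all(np.isfinite(ll)):
                    bad = int(np.flatnonzero(~np.isfinite(ll))[0])
                    raise FloatingPointError(
                        f"non-finite vine density at row {bad}, edge {e} ({cop})")
                out += ll
            if not is_last:
                pseudo[(e.a, e.conditioning | {e.b})] = bicop_hfunc(cop, u1, u2, "second")
                pseudo[(e.b, e.conditioning | {e.a})] = bicop_hfunc(cop, u1, u2, "first")
    return out


# ----------------------------------------------------------------------
# peeling decomposition (also yields the structure-matrix serialization)
# ----------------------------------------------------------------------

def _peel_columns(structure: RVineStructure):
    """Peel leaf variables off the vine one at a time.

    Returns ``(order, cols)`` where ``cols[k] = (var, [edges])`` lists, for the
    k-th peeled variable, its unique edge in each remaining tree (tree order
    1..m).  The reversed order is a valid sampling order for the
    inverse-Rosenblatt transform.  Requires a structurally complete vine
    (n-1 trees).
    """
    n = structure.n
    if len(structure.trees) != n - 1:
        raise StructureError("peeling requires a complete structure (n-1 trees); "
                             "complete truncated trees with independence edges first")
    trees = [list(t) for t in structure.trees]
    cols = []
    remaining = set(range(n))
    while len(remaining) > 1:
        m = len(remaining) - 1
        top = trees[m - 1]
        if len(top) != 1:
            raise StructureError("invalid vine: top tree of sub-vine is not a single edge")
        candidates = (top[0].a, top[0].b)
        peeled = None
        for a in candidates:
            per_tree = []
            for t in range(m):
                hits = [e for e in trees[t] if a in (e.a, e.b)]
                if len(hits) != 1:
                    per_tree = None
                    break
                per_tree.append(hits[0])
            if per_tree is not None:
                peeled = (a, per_tree)
                break
        if peeled is None:
            raise StructureError("invalid vine: no peelable variable in top conditioned pair")
        a, per_tree = peeled
        cols.append((a, per_tree))
        for t, e in enumerate(per_tree):
            trees[t].remove(e)
        remaining.discard(a)
    last = remaining.pop()
    order = [v for v, _ in cols] + [last]
    return order, cols


def structure_matrix(structure: RVineStructure) -> np.ndarray:
    """Lower-triangular R-vine matrix (1-based variable labels).

    Column j holds the j-th peeled variable on the diagonal and its partners
    in trees 1..n-j from the bottom row upward; this is the standard compact
    array encoding of a vine structure.
    """
    n = structure.n
    order, cols = _peel_columns(structure)
    M = np.zeros((n, n), dtype=int)
    for j, (a, per_tree) in enumerate(cols):
        M[j, j] = a + 1
        for t, e in enumerate(per_tree):  # t = tree-1 index
            partner = e.b if e.a == a else e.a
            M[n - 1 - t, j] = partner + 1
    M[n - 1, n - 1] = order[-1] + 1
    return M


# ----------------------------------------------------------------------
# sampling
# ----------------------------------------------------------------------

def _complete_structure(m: RVineModel) -> RVineModel:
    """Extend a structurally incomplete (truncated) model to n-1 trees by
    adding proximity-valid independence edges."""
    import networkx as nx

    trees = [list(t) for t in m.structure.trees]
    cops = [list(c) for c in m.copulas]
    n = m.n
    if not trees and n > 1:  # fully truncated model: start from a path
        trees.append([VineEdge(i, i + 1) for i in range(n - 1)])
        cops.append([INDEPENDENCE] * (n - 1))
    while len(trees) < n - 1:
        prev = trees[-1]
        g = nx.Graph()
        g.add_nodes_from(range(len(prev)))
        for i, p in enumerate(prev):
            for j in range(i + 1, len(prev)):
                q = prev[j]
                # adjacency of two tree-t edges: variable sets overlap in t vars
                if len(p.variables & q.variables) == len(p.conditioning) + 1:
                    g.add_edge(i, j)
        st = nx.minimum_spanning_tree(g)
        if st.number_of_edges() != len(prev) - 1:
            raise StructureError("cannot complete truncated structure")
        tree = []
        for i, j in sorted(st.edges()):
            p, q = prev[i], prev[j]
            cond = p.variables & q.variables
            a, b = sorted(p.variables ^ q.variables)
            tree.append(VineEdge(a, b, cond))
        trees.append(tree)
        cops.append([INDEPENDENCE] * len(tree))
    return RVineModel(RVineStructure(n, trees), cops, m.truncation_level)


def rvine_sample(m: RVineModel, n_samples: int, seed=None, rng=None) -> np.ndarray:
    """Draw samples from the vine copula by the inverse-Rosenblatt transform.

    Variables are added in the reverse of a peeling order; each new variable's
    uniform driver is pushed back through the h-function chain of its edges
    (top tree first), and the pseudo-observation cache is extended exactly as
    in the density recursion.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(m.structure.trees) < m.n - 1:
        m = _complete_structure(m)
    order, cols = _peel_columns(m.structure)
    cop_of = {e.key(): c for e, c in m.edges()}

    W = rng.uniform(size=(n_samples, m.n))
    pseudo = {}
    U = np.empty((n_samples, m.n))

    seq = [(order[-1], [])] + list(reversed(cols))
    present = set()
    for k, (v, edges) in enumerate(seq):
        z = W[:, k]
        for e in reversed(edges):  # top tree first
            cop = cop_of[e.key()]
            partner = e.b if e.a == v else e.a
            cond_u = pseudo[(partner, e.conditioning)]
            if e.a == v:
                z = bicop_hinv(cop, z, cond_u, "second")
            else:
                z = bicop_hinv(cop, z, cond_u, "first")
        U[:, v] = z
        pseudo[(v, frozenset())] = z
        present.add(v)
        # extend the pseudo-observation cache over the enlarged variable set
        for tree, cops in zip(m.structure.trees, m.copulas):
            for e, cop in zip(tree, cops):
                key_a = (e.a, e.conditioning | {e.b})
                if e.variables <= present and key_a not in pseudo:
                    u1 = pseudo[(e.a, e.conditioning)]
                    u2 = pseudo[(e.b, e.conditioning)]
                    pseudo[key_a] = bicop_hfunc(cop, u1, u2, "second")
                    pseudo[(e.b, e.conditioning | {e.a})] = bicop_hfunc(cop, u1, u2, "first")
    return U


# ----------------------------------------------------------------------
# truncation & parameter counting
# ----------------------------------------------------------------------

def truncate_model(m: RVineModel, level: int) -> RVineModel:
    """Replace all pair-copulas above ``level`` with independence."""
    if not (0 <= level <= m.n - 1):
        raise ValueError(f"truncation level {level} out of [0, {m.n - 1}]")
    cops = [
        list(c) if t < level else [INDEPENDENCE] * len(c)
        for t, c in enumerate(m.copulas)
    ]
    return RVineModel(m.structure, cops, truncation_level=min(level, len(m.structure.trees)))


def count_parameters(vines, margins=None, n_components_weights: int = 0) -> int:
    """Total parameter count delta of a (mixture of) vine model(s).

    ``vines`` is an RVineModel or list of them; ``margins`` a matching list of
    per-component margin lists.  Mixture weights contribute G-1 parameters.
    """
    if isinstance(vines, RVineModel):
        vines = [vines]
    total = 0
    for g, vine in enumerate(vines):
        total += vine.n_copula_params()
        if margins is not None:
            total += sum(m.n_params for m in margins[g])
    if n_components_weights > 1:
        total += n_components_weights - 1
    return total
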