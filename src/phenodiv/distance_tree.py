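"""Genetic distances and neighbour-joining trees.

Two distance layers:

* genotype level — pairwise trait-mismatch proportion on one-hot profiles
  (fraction of co-scored traits at which two genotypes carry different
  states), optionally transformed to ``-ln(1 - m)``. For one-hot categorical
  profiles any Nei-type identity is a monotone function of the mismatch
  proportion, so the NJ topology does not depend on this choice.
* group level — Nei (1972) standard genetic identity/distance from per-group
  state frequencies, ``I = J_xy / sqrt(J_x J_y)``, ``D = -ln I``, with the
  per-trait J terms averaged across traits; the 1978 small-sample correction
  for a single observation per genotype is available via ``unbiased=True``.

Neighbour joining is the classic Saitou–Nei agglomeration with the canonical
Q-criterion and branch-length formulas, a deterministic tie-break (the
lexicographically smallest label pair wins), and clamp-and-transfer handling
of negative branch lengths. Trees are unrooted; newick serialization roots
arbitrarily at the last internal node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .matrix import BinaryMatrix, FrequencyTable

__all__ = [
    "DistanceMatrix",
    "Tree",
    "genotype_distance",
    "group_nei_distance",
    "neighbor_joining",
    "write_newick",
    "read_newick",
    "cluster_report",
]

PathLike = Union[str, Path]


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix; NaN marks an undefined pair."""

    labels: list[str]
    d: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix has a nonzero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def write_tsv(self, path: PathLike, header: str = "") -> None:
        lines = [f"# {h}" for h in header.splitlines() if header]
        lines.append("\t".join(["id"] + self.labels))
        for lab, row in zip(self.labels, self.d):
            lines.append("\t".join([lab] + [f"{x:.6f}" for x in row]))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    def write_phylip(self, path: PathLike) -> None:
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.d):
            name = lab[:10].ljust(10)
            lines.append(name + "  " + "  ".join(f"{x:.6f}" for x in row))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def genotype_distance(bm: BinaryMatrix, metric: str = "mismatch") -> DistanceMatrix:
    """Pairwise distances among genotypes from their one-hot profiles.

    ``mismatch``: proportion of co-scored traits with differing states.
    ``neilog``: ``-ln(1 - m)``; identical profiles give 0, fully mismatched
    pairs give +inf. Pairs with no co-scored trait get NaN.
    """
    s = bm.state_idx
    scored = s != -1
    both = scored[:, None, :] & scored[None, :, :]
    same = (s[:, None, :] == s[None, :, :]) & both
    n_both = both.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = 1.0 - same.sum(axis=2) / n_both
    m[n_both == 0] = np.nan
    np.fill_diagonal(m, 0.0)
    if metric == "mismatch":
        d = m
    elif metric == "neilog":
        with np.errstate(divide="ignore"):
            d = -np.log(1.0 - m)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(labels=list(bm.ids), d=d, metric_name=metric)


def group_nei_distance(
    fts: dict[str, FrequencyTable], unbiased: bool = False
) -> DistanceMatrix:
    """Nei genetic distance among groups from per-group state frequencies.

    J_x is the across-trait mean of ``sum_i x_i^2`` (with the haploid
    small-sample correction ``(n sum x^2 - 1)/(n - 1)`` when ``unbiased``,
    floored at a small positive value); J_xy the mean of ``sum_i x_i y_i``.
    Identity ``I = J_xy / sqrt(J_x J_y)``; ``D = -ln I`` (+inf when I <= 0).
    """
    groups = list(fts)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    cat = fts[groups[0]].catalog
    t_keys = cat.trait_keys

    def j_self(ft: FrequencyTable) -> float:
        vals = []
        for k in t_keys:
            p = ft.p[k]
            j = float(np.sum(p * p))
            if unbiased:
                n = ft.n[k]
                if n < 2:
                    raise ValueError(f"unbiased Nei distance needs n >= 2 per trait ({k})")
                j = max((n * j - 1.0) / (n - 1.0), 1e-12)
            vals.append(j)
        return float(np.mean(vals))

    js = {g: j_self(fts[g]) for g in groups}
    n = len(groups)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            jxy = float(
                np.mean([np.sum(fts[groups[a]].p[k] * fts[groups[b]].p[k]) for k in t_keys])
            )
            ident = jxy / np.sqrt(js[groups[a]] * js[groups[b]])
            if ident <= 0:
                warnings.warn(
                    f"zero identity between {groups[a]!r} and {groups[b]!r}; "
                    "distance is infinite",
                    stacklevel=2,
                )
                dist = np.inf
            else:
                dist = -np.log(ident)
            d[a, b] = d[b, a] = dist
    return DistanceMatrix(labels=groups, d=d, metric_name="nei_unbiased" if unbiased else "nei")


# ---------------------------------------------------------------------------
# trees


@dataclass
class Tree:
    """Unrooted tree as an undirected adjacency map with branch lengths."""

    adj: dict[int, list[tuple[int, float]]] = field(default_factory=dict)
    leaf_labels: dict[int, str] = field(default_factory=dict)
    root: int = 0  # serialization anchor only; the tree is unrooted

    def add_edge(self, a: int, b: int, length: float) -> None:
        self.adj.setdefault(a, []).append((b, length))
        self.adj.setdefault(b, []).append((a, length))

    @property
    def leaves(self) -> list[str]:
        return [self.leaf_labels[n] for n in sorted(self.leaf_labels)]

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf patristic distance matrix, labels in sorted order."""
        leaf_nodes = sorted(self.leaf_labels, key=lambda n: self.leaf_labels[n])
        labels = [self.leaf_labels[n] for n in leaf_nodes]
        pos = {n: i for i, n in enumerate(leaf_nodes)}
        k = len(leaf_nodes)
        d = np.zeros((k, k))
        for start in leaf_nodes:
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, ln in self.adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + ln
                        stack.append(v)
            for n2, x in dist.items():
                if n2 in pos:
                    d[pos[start], pos[n2]] = x
        return DistanceMatrix(labels=labels, d=d, metric_name="patristic")

    def to_newick(self) -> str:
        def fmt_label(lab: str) -> str:
            if any(c in lab for c in "()[]:;, '\t\n"):
                return "'" + lab.replace("'", "''") + "'"
            return lab

        def rec(node: int, parent: Optional[int]) -> str:
            children = [(v, ln) for v, ln in self.adj[node] if v != parent]
            if not children:
                return fmt_label(self.leaf_labels[node])
            inner = ",".join(f"{rec(v, node)}:{ln:.10g}" for v, ln in children)
            name = fmt_label(self.leaf_labels[node]) if node in self.leaf_labels else ""
            return f"({inner}){name}"

        return rec(self.root, None) + ";"


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbour joining on a complete finite distance matrix.

    Ties in the Q criterion (within 1e-12) resolve to the pair whose sorted
    representative labels are lexicographically smallest, where an internal
    cluster is represented by the smallest leaf label beneath it. Negative
    branch lengths are clamped to zero with the deficit transferred to the
    sister branch, preserving the pair's summed length.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 labels")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError(
            "distance matrix has missing or infinite entries; impute or subset first"
        )
    tree = Tree()
    for i, lab in enumerate(dm.labels):
        tree.leaf_labels[i] = lab
        tree.adj.setdefault(i, [])

    active = list(range(n))
    names = {i: dm.labels[i] for i in range(n)}  # tie-break representatives
    d = {(i, j): float(dm.d[i, j]) for i in range(n) for j in range(n) if i < j}

    def dist(a: int, b: int) -> float:
        return d[(a, b) if a < b else (b, a)]

    next_node = n
    while len(active) > 3:
        r = len(active)
        row_sum = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        best_q = np.inf
        for ia in range(r):
            for ib in range(ia + 1, r):
                a, b = active[ia], active[ib]
                q = (r - 2) * dist(a, b) - row_sum[a] - row_sum[b]
                pair_key = tuple(sorted((names[a], names[b])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and best is not None and pair_key < best[1]
                ):
                    best_q = q
                    best = ((a, b), pair_key)
        (a, b), _ = best
        dab = dist(a, b)
        va = 0.5 * dab + (row_sum[a] - row_sum[b]) / (2.0 * (r - 2))
        vb = dab - va
        if va < 0:
            vb += va
            va = 0.0
        if vb < 0:
            va += vb
            vb = 0.0
        u = next_node
        next_node += 1
        tree.add_edge(u, a, va)
        tree.add_edge(u, b, vb)
        names[u] = min(names[a], names[b])
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist(a, c) + dist(b, c) - dab)
            d[(min(u, c), max(u, c))] = duc
        active = [c for c in active if c not in (a, b)] + [u]

    a, b, c = active
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    va = 0.5 * (dab + dac - dbc)
    vb = 0.5 * (dab + dbc - dac)
    vc = 0.5 * (dac + dbc - dab)
    center = next_node
    for node, v in ((a, va), (b, vb), (c, vc)):
        tree.add_edge(center, node, max(v, 0.0))
    tree.root = center
    return tree


def write_newick(tree: Tree, path: PathLike) -> None:
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


def read_newick(path_or_string: Union[PathLike, str]) -> Tree:
    """Parse a newick tree (via dendropy) into the package's unrooted form."""
    import dendropy

    s = str(path_or_string)
    if "(" in s and ";" in s:
        dt = dendropy.Tree.get(data=s, schema="newick")
    else:
        dt = dendropy.Tree.get(path=s, schema="newick")
    tree = Tree()
    node_id: dict = {}
    for i, nd in enumerate(dt.preorder_node_iter()):
        node_id[nd] = i
        tree.adj.setdefault(i, [])
        if nd.is_leaf():
            tree.leaf_labels[i] = nd.taxon.label
    for nd in dt.preorder_node_iter():
        if nd.parent_node is not None:
            ln = nd.edge.length if nd.edge.length is not None else 0.0
            tree.add_edge(node_id[nd.parent_node], node_id[nd], float(ln))
    tree.root = node_id[dt.seed_node]
    return tree


def cluster_report(tree: Tree, edge: Optional[tuple[int, int]] = None) -> tuple[list[str], list[str]]:
    """Bipartition the leaves by cutting an edge (default: longest internal edge)."""
    if edge is None:
        best = None
        best_len = -1.0
        for u, nbrs in tree.adj.items():
            for v, ln in nbrs:
                if u < v and u not in tree.leaf_labels and v not in tree.leaf_labels:
                    if ln > best_len:
                        best_len, best = ln, (u, v)
        if best is None:  # no internal edge (e.g. a single star): fall back to longest edge
            for u, nbrs in tree.adj.items():
                for v, ln in nbrs:
                    if u < v and ln > best_len:
                        best_len, best = ln, (u, v)
        edge = best
    u, v = edge
    side: list[str] = []
    seen = {v, u}
    stack = [u]
    while stack:
        x = stack.pop()
        if x in tree.leaf_labels:
            side.append(tree.leaf_labels[x])
        for y, _ in tree.adj[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    other = [lab for lab in tree.leaves if lab not in side]
    return sorted(side), sorted(other)
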