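"""Pairwise divergence and neighbor-joining for hominin sequences.

Distances are raw per-site mismatch proportions (p-distance); at hominin
divergences of ~0.002 a multiple-hit correction changes the third decimal of
nothing, but a Jukes-Cantor option is provided. The tree is built by
Saitou-Nei neighbor joining with the standard Q-criterion, deterministic
ties broken by taxon-label order; branch support is the count of bootstrap
replicates (column resampling) whose NJ tree contains each internal
bipartition of the point-estimate tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignment import NUCS


@dataclass
class DistanceMatrix:
    """Symmetric per-site divergence matrix with per-pair site counts."""

    labels: list[str]
    matrix: np.ndarray
    n_sites: np.ndarray = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.labels)
        if self.matrix.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.matrix)) > 1e-12):
            raise ValueError("distance matrix has non-zero diagonal")
        if self.n_sites is None:
            self.n_sites = np.zeros((k, k), dtype=np.int64)

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def haploidize(gt: np.ndarray, ref: np.ndarray, alt: np.ndarray,
               seed: int) -> np.ndarray:
    """Collapse one diploid's biallelic genotypes to a haploid allele vector.

    Homozygous sites pass through; at heterozygous sites one of the two
    alleles is chosen uniformly at random (deterministic under `seed`).
    Missing genotypes yield 'N'.
    """
    gt = np.asarray(gt)
    ref = np.asarray(ref, dtype="<U1")
    alt = np.asarray(alt, dtype="<U1")
    rng = np.random.default_rng(seed)
    pick_alt = rng.random(gt.size) < 0.5
    out = np.where(gt == 0, ref,
                   np.where(gt == 2, alt,
                            np.where(gt == 1, np.where(pick_alt, alt, ref),
                                     "N")))
    return out.astype("<U1")


def sequence_from_genotypes(ref_seq: np.ndarray, pos: np.ndarray,
                            alleles: np.ndarray) -> np.ndarray:
    """Paint per-site haploidized alleles onto a copy of the reference."""
    seq = np.asarray(ref_seq, dtype="<U1").copy()
    seq[np.asarray(pos, dtype=np.int64)] = alleles
    return seq


def pairwise_divergence(seq_a: np.ndarray, seq_b: np.ndarray,
                        joint_mask: np.ndarray | None = None,
                        jukes_cantor: bool = False) -> tuple[float, int]:
    """(per-site divergence, jointly scored sites) between two equal-length
    sequences; only positions where both carry a plain base (and pass the
    joint mask, if given) are scored."""
    a = np.asarray(seq_a, dtype="<U1")
    b = np.asarray(seq_b, dtype="<U1")
    if a.size != b.size:
        raise ValueError("sequences differ in length")
    ok = np.isin(a, NUCS) & np.isin(b, NUCS)
    if joint_mask is not None:
        ok &= np.asarray(joint_mask, dtype=bool)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no jointly scored sites")
    p = float((a[ok] != b[ok]).mean())
    if jukes_cantor:
        p = -0.75 * np.log1p(-4.0 * p / 3.0)
    return p, n


def distance_matrix(seqs: Mapping[str, np.ndarray],
                    joint_mask: np.ndarray | None = None,
                    jukes_cantor: bool = False) -> DistanceMatrix:
    labels = list(seqs)
    k = len(labels)
    d = np.zeros((k, k))
    n = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(i + 1, k):
            dij, nij = pairwise_divergence(seqs[labels[i]], seqs[labels[j]],
                                           joint_mask, jukes_cantor)
            d[i, j] = d[j, i] = dij
            n[i, j] = n[j, i] = nij
    return DistanceMatrix(labels, d, n)


@dataclass
class NJTree:
    """Unrooted tree as an adjacency map node -> [(neighbor, length), ...].

    Leaves carry their taxon labels; internal nodes are numbered strings.
    """

    adjacency: dict[str, list[tuple[str, float]]]
    leaves: list[str]

    def neighbors(self, node: str):
        return self.adjacency[node]

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalised as the side not
        containing the first leaf (sorted by label)."""
        anchor = min(self.leaves)
        parts = set()
        for a, nbrs in self.adjacency.items():
            for b, _ in nbrs:
                if a >= b:
                    continue
                side = self._leafset(b, a)
                if anchor in side:
                    side = frozenset(self.leaves) - side
                if 1 < len(side) < len(self.leaves) - 1:
                    parts.add(frozenset(side))
        return parts

    def _leafset(self, start: str, blocked: str) -> frozenset:
        seen, stack, out = {blocked, start}, [start], []
        while stack:
            node = stack.pop()
            if node in self.leaves:
                out.append(node)
            for nbr, _ in self.adjacency[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return frozenset(out)

    def to_newick(self, root_on: str | None = None) -> str:
        """Newick string, optionally rooted on an outgroup leaf for display."""
        if root_on is None:
            root_on = min(self.leaves)
        if root_on not in self.leaves:
            raise ValueError(f"unknown outgroup {root_on!r}")

        def render(node: str, parent: str) -> str:
            kids = [(n, l) for n, l in self.adjacency[node] if n != parent]
            if not kids:
                return node
            inner = ",".join(f"{render(n, node)}:{l:.10g}" for n, l in kids)
            return f"({inner})"

        (hub, blen), = [e for e in self.adjacency[root_on]]
        return f"({root_on}:{blen:.10g},{render(hub, root_on)}:0);"

    def leaf_path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        dist = {a: 0.0}
        stack = [a]
        while stack:
            node = stack.pop()
            for nbr, l in self.adjacency[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + l
                    stack.append(nbr)
        return dist[b]


def nj_tree(dm: DistanceMatrix) -> NJTree:
    """Saitou-Nei neighbor joining with deterministic label-order
    tie-breaking on the Q-criterion."""
    k = len(dm.labels)
    if k < 3:
        raise ValueError("need at least 3 taxa")
    active = list(dm.labels)
    # node label -> distances to other active nodes
    d = {a: {b: dm.matrix[i, j] for j, b in enumerate(dm.labels) if a != b}
         for i, a in enumerate(dm.labels)}
    adjacency: dict[str, list[tuple[str, float]]] = {a: [] for a in active}
    sort_key = {a: (0, a) for a in active}  # leaves sort before internals by label
    counter = 0

    def connect(a: str, b: str, length: float) -> None:
        length = max(length, 0.0)
        adjacency[a].append((b, length))
        adjacency[b].append((a, length))

    while len(active) > 3:
        r = len(active)
        totals = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        ordered = sorted(active, key=lambda a: sort_key[a])
        for i, a in enumerate(ordered):
            for b in ordered[i + 1:]:
                q = (r - 2) * d[a][b] - totals[a] - totals[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        u = f"__nj{counter}"
        counter += 1
        la = 0.5 * d[a][b] + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = d[a][b] - la
        adjacency[u] = []
        sort_key[u] = (1, u)
        connect(a, u, la)
        connect(b, u, lb)
        d[u] = {}
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
            d[u][c] = d[c][u] = duc
        active = [c for c in active if c not in (a, b)] + [u]

    a, b, c = sorted(active, key=lambda x: sort_key[x])
    u = f"__nj{counter}"
    adjacency[u] = []
    connect(a, u, 0.5 * (d[a][b] + d[a][c] - d[b][c]))
    connect(b, u, 0.5 * (d[a][b] + d[b][c] - d[a][c]))
    connect(c, u, 0.5 * (d[a][c] + d[b][c] - d[a][b]))
    return NJTree(adjacency=adjacency, leaves=list(dm.labels))


def bootstrap_support(seqs: Mapping[str, np.ndarray], n_reps: int = 100,
                      seed: int = 0,
                      joint_mask: np.ndarray | None = None,
                      ) -> dict[frozenset, int]:
    """Column-bootstrap support, out of `n_reps`, for each internal
    bipartition of the point-estimate NJ tree."""
    labels = list(seqs)
    if len(labels) < 4:
        raise ValueError("need at least 4 taxa for internal branches")
    mat = np.vstack([np.asarray(seqs[l], dtype="<U1") for l in labels])
    if joint_mask is not None:
        mat = mat[:, np.asarray(joint_mask, dtype=bool)]
    point = nj_tree(distance_matrix({l: mat[i] for i, l in enumerate(labels)}))
    target = point.bipartitions()
    support = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    n_cols = mat.shape[1]
    for _ in range(n_reps):
        idx = rng.integers(0, n_cols, size=n_cols)
        rep = mat[:, idx]
        dm = distance_matrix({l: rep[i] for i, l in enumerate(labels)})
        parts = nj_tree(dm).bipartitions()
        for bp in target:
            if bp in parts:
                support[bp] += 1
    return support
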