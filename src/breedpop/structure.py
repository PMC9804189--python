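"""Between-individual genetic structure: IBS distance, classical MDS, and
neighbor-joining trees.

The identity-by-state (IBS) distance between two genotype vectors is
1 - mean allele sharing over markers typed in both samples.  Classical
(Torgerson) multidimensional scaling embeds the distance matrix via the
double-centred Gram matrix; neighbor joining (Saitou & Nei) builds an
unrooted tree, exact for additive distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if np.any(self.d < -1e-12):
            raise ValueError("negative distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def ibs_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """1 - IBS allele sharing for every sample pair.

    Sharing at a marker is (2 - |g_a - g_b|) / 2; markers missing in either
    sample are excluded pairwise.  A pair with no shared typed marker is an
    error.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    g = gm.calls.astype(float)
    obs = gm.calls != MISSING
    g0 = np.where(obs, g, 0.0)
    o = obs.astype(float)

    # sum over shared markers of |ga - gb| expanded pairwise: use the identity
    # |x - y| for x,y in {0,1,2}: |x-y| = x + y - 2*min(x,y); min needs care,
    # so compute via indicator matrices per dosage instead.
    ind = [(gm.calls == k).astype(float) for k in (0, 1, 2)]
    n_shared = o @ o.T
    # |ga-gb| summed = sum_k sum_l |k-l| * (#markers with ga=k, gb=l, both obs)
    absdiff = np.zeros((gm.n_samples, gm.n_samples))
    for k in range(3):
        for l in range(3):
            if k == l:
                continue
            absdiff += abs(k - l) * (ind[k] @ ind[l].T)
    if np.any((n_shared == 0) & ~np.eye(gm.n_samples, dtype=bool)):
        i, j = np.argwhere((n_shared == 0) & ~np.eye(gm.n_samples, dtype=bool))[0]
        raise ValueError(
            f"samples {gm.sample_ids[i]!r} and {gm.sample_ids[j]!r} share no typed markers"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = absdiff / (2.0 * n_shared)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry
    return DistanceMatrix(list(gm.sample_ids), d)


def classical_mds(D: DistanceMatrix, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson classical scaling of a distance matrix.

    Returns (coordinates n x k, eigenvalues descending).  Coordinates are
    eigenvectors scaled by sqrt(eigenvalue); a negative eigenvalue among the
    top k (non-Euclidean input) is an error.  Each axis's sign is fixed so
    its first nonzero coordinate is positive.
    """
    n = len(D.ids)
    if n <= k:
        raise ValueError("need more points than dimensions")
    d2 = D.d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    top = evals[:k]
    if np.any(top < -1e-9 * max(1.0, abs(evals[0]))):
        raise ValueError("negative eigenvalue among the top k: distances not Euclidean")
    coords = evecs[:, :k] * np.sqrt(np.clip(top, 0.0, None))
    for axis in range(k):
        col = coords[:, axis]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return coords, evals


# ----------------------------------------------------------------------
# neighbor joining
# ----------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name] if self.name is not None else []
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary internal root node."""

    root: TreeNode
    n_clamped: int = 0  # negative NJ branch estimates clamped to zero

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def leaf_distances(self) -> pd.DataFrame:
        """Path-length distances between all leaf pairs."""
        names = self.leaves()
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))

        # collect leaf distances below each node, combine at internal nodes
        def walk(node: TreeNode) -> list[tuple[str, float]]:
            if not node.children:
                return [(node.name, 0.0)]
            groups = []
            for child, bl in node.children:
                groups.append([(nm, dist + bl) for nm, dist in walk(child)])
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for nm_a, da in groups[gi]:
                        for nm_b, db in groups[gj]:
                            d[idx[nm_a], idx[nm_b]] = d[idx[nm_b], idx[nm_a]] = da + db
            return [x for g in groups for x in g]

        walk(self.root)
        return pd.DataFrame(d, index=names, columns=names)


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimising Q_ij = (n-2) d_ij - r_i - r_j is joined at every
    step (smallest (i, j) index pair on ties); negative branch-length
    estimates are clamped to zero and counted on the returned tree.
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in D.ids]
    d = D.d.copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d_next = np.zeros((m - 1, m - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = new_d[keep]
        nodes = [nodes[x] for x in keep] + [parent]
        d = d_next

    # final three-way join: closed-form branch lengths
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode(children=[(nodes[0], clamp(la)), (nodes[1], clamp(lb)),
                              (nodes[2], clamp(lc))])
    return Tree(root=root, n_clamped=clamped)


def write_newick(tree: Tree) -> str:
    """Serialise a tree as Newick with 6-significant-digit branch lengths."""

    def quote(name: str) -> str:
        if any(c in name for c in " \t()[]:;,'"):
            return "'" + name.replace("'", "''") + "'"
        return name

    def fmt(node: TreeNode) -> str:
        if not node.children:
            return quote(node.name)
        inner = ",".join(f"{fmt(c)}:{bl:.6g}" for c, bl in node.children)
        return f"({inner})"

    return fmt(tree.root) + ";"


def write_distance_tsv(D: DistanceMatrix, path: str | Path) -> None:
    D.to_frame().to_csv(path, sep="\t")
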