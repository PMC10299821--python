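"""Population structure: genotype PCA, allele-sharing distances and
neighbor-joining trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "PCAResult",
    "pca_genotypes",
    "DistanceMatrix",
    "genetic_distance",
    "nj_tree",
]


@dataclass
class PCAResult:
    samples: list[str]
    scores: np.ndarray
    loadings: np.ndarray
    explained: np.ndarray


def pca_genotypes(
    g: GenotypeMatrix, n_components: int = 10, scaling: str = "patterson"
) -> PCAResult:
    """PCA of mean-imputed genotype dosages.

    ``patterson`` scaling divides each centered site by sqrt(p(1-p)) with
    p the mean alt-allele frequency, the standard normalization for SNP
    PCA; ``unit`` leaves sites unscaled.  Component signs are fixed so the
    largest-magnitude loading of each axis is positive (determinism).
    """
    gv = g.variant_only()
    if gv.n_samples < 2 or gv.n_sites < 2:
        raise ValueError("need at least 2 samples and 2 variant sites")
    d = gv.dosages_imputed()  # sites x samples
    mean = d.mean(axis=1, keepdims=True)
    x = d - mean
    if scaling == "patterson":
        p = np.clip(mean[:, 0] / 2.0, 0.0, 1.0)
        denom = np.sqrt(p * (1 - p))
        keep = denom > 0
        x = x[keep] / denom[keep, None]
    elif scaling == "unit":
        keep = x.std(axis=1) > 0
        x = x[keep]
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    if x.shape[0] == 0 or not np.any(x):
        raise ValueError("zero-variance input")
    # samples x sites orientation for the sample-covariance eigenproblem
    xt = x.T
    u, s, vt = np.linalg.svd(xt - xt.mean(axis=0), full_matrices=False)
    k = min(n_components, len(s))
    total = np.sum(s**2)
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    for j in range(k):  # deterministic sign
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        samples=list(gv.samples),
        scores=scores,
        loadings=loadings,
        explained=(s[:k] ** 2) / total,
    )


# ----------------------------------------------------------------------
@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix does not match label count")
        if np.any(np.abs(self.values - self.values.T) > 1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be exactly zero")

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels=list(labels), values=self.values[np.ix_(idx, idx)])


def genetic_distance(g: GenotypeMatrix, metric: str = "allele_sharing") -> DistanceMatrix:
    """Pairwise allele-sharing distance over pairwise-complete sites.

    Per site a pair of diploids shares alleles in proportion
    1 - |dosage_i - dosage_j| / 2; the distance is one minus the mean
    shared proportion, i.e. mean(|d_i - d_j|) / 2.
    """
    if metric != "allele_sharing":
        raise ValueError(f"unknown metric {metric!r}")
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    calls = g.calls.astype(float)
    obs = g.calls != MISSING
    n = g.n_samples
    dist = np.zeros((n, n))
    for i in range(n):
        both = obs[:, i, None] & obs[:, i + 1 :]
        diff = np.abs(calls[:, i, None] - calls[:, i + 1 :])
        with np.errstate(invalid="ignore"):
            counts = both.sum(axis=0)
            if np.any(counts == 0):
                bad = np.flatnonzero(counts == 0)
                raise ValueError(
                    f"sample pair ({g.samples[i]}, {g.samples[i + 1 + bad[0]]}) "
                    "has no co-observed sites"
                )
            d = np.where(both, diff, 0.0).sum(axis=0) / counts / 2.0
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
    return DistanceMatrix(labels=list(g.samples), values=dist)


# ----------------------------------------------------------------------
def nj_tree(d: DistanceMatrix, outgroup: str | None = None) -> str:
    """Saitou–Nei neighbor joining; returns a newick string.

    Ties in the Q-matrix are broken by the smallest (i, j) label pair, so
    the output is deterministic.  Negative branch lengths are clamped to
    zero with the deficit transferred to the sister edge (pairwise path
    lengths preserved).  The tree is unrooted; for output it is rooted at
    the midpoint of the outgroup's pendant edge when ``outgroup`` is
    given, otherwise at the last join.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if outgroup is not None and outgroup not in d.labels:
        raise ValueError(f"outgroup {outgroup!r} not among labels")
    names: dict[int, str] = {i: l for i, l in enumerate(d.labels)}
    adj: dict[int, dict[int, float]] = {i: {} for i in range(n)}

    dm = d.values.copy()
    active = list(range(n))
    next_id = n
    while len(active) > 2:
        m = len(active)
        sub = dm[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                key = (q[a, b], a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        u = next_id
        next_id += 1
        adj[u] = {}
        adj[u][i] = adj[i][u] = max(li, 0.0)
        adj[u][j] = adj[j][u] = max(lj, 0.0)
        dm = np.pad(dm, ((0, 1), (0, 1)))
        for c in active:
            if c in (i, j):
                continue
            dm[u, c] = dm[c, u] = 0.5 * (dm[i, c] + dm[j, c] - dij)
        active = [c for c in active if c not in (i, j)] + [u]
    i, j = active
    final = max(dm[i, j], 0.0)
    adj[i][j] = final
    adj[j][i] = final

    # choose the root: midpoint of the outgroup pendant edge, or last join
    root = next_id
    if outgroup is not None:
        leaf = d.labels.index(outgroup)
        nb = next(iter(adj[leaf]))
        half = adj[leaf][nb] / 2.0
        del adj[leaf][nb]
        del adj[nb][leaf]
        adj[root] = {leaf: half, nb: half}
        adj[leaf][root] = half
        adj[nb][root] = half
    else:
        half = adj[i][j]
        del adj[i][j]
        del adj[j][i]
        adj[root] = {i: half / 2.0, j: half / 2.0}
        adj[i][root] = half / 2.0
        adj[j][root] = half / 2.0

    def emit(node: int, parent: int | None) -> str:
        children = sorted(k for k in adj[node] if k != parent)
        if not children:
            return names.get(node, "")
        inner = ",".join(
            f"{emit(c, node)}:{adj[node][c]:.10g}" for c in children
        )
        return f"({inner}){names.get(node, '')}"

    return emit(root, None) + ";"
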