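"""f2 / f3 / f4 statistics with weighted block-jackknife standard errors.

The f-statistics are quadratic forms in population allele frequencies that
measure shared genetic drift.  Per-site contributions (with p-hat the
sample alt-allele frequency and n the called allele copies):

* f2(A, B)     = (pA - pB)^2 - Var(pA) - Var(pB)
* f3(C; A, B)  = (pC - pA)(pC - pB) - Var(pC)
* f4(A, B; C, D) = (pA - pB)(pC - pD)            (no bias term needed)

The Var(p) bias terms are estimated from the sample variance of genotype
dosages (s^2 / 4N), which stays unbiased under inbreeding; for outbred
samples it equals the familiar heterozygosity/n correction in expectation.

Estimates average per-site contributions over sites with complete coverage
in the populations involved.  Standard errors come from a delete-one block
jackknife over contiguous genomic blocks (2 Mb by default) weighted by
per-block site counts; |Z| > 3 is the conventional significance call.
A significantly negative f3(C; A, B) indicates C is admixed between A-like
and B-like sources; a nonzero f4 rejects the tested unrooted tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .diversity import pop_site_stats
from .genotypes import GenotypeMatrix

__all__ = [
    "FStatResult",
    "f_statistic",
    "classify_significance",
    "admixture_f3_scan",
    "weighted_block_jackknife",
]


@dataclass
class FStatResult:
    kind: str
    pops: tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_sites: int
    block_bp: int

    def __str__(self) -> str:  # pragma: no cover
        pops = ",".join(self.pops)
        return (
            f"{self.kind}({pops}) = {self.estimate:.6g} "
            f"(SE {self.se:.3g}, Z {self.z:.3f}, {self.n_blocks} blocks)"
        )


def weighted_block_jackknife(values: np.ndarray, weights: np.ndarray):
    """Delete-one block jackknife for a weighted mean.

    ``values`` are per-block means, ``weights`` per-block site counts.
    Returns (estimate, SE) using the weighted jackknife of Busing et al.:
    pseudovalues tau_j = h_j * theta - (h_j - 1) * theta_(-j) with
    h_j = n / m_j, and variance (1/g) * sum (tau_j - theta_J)^2 / (h_j - 1).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    keep = weights > 0
    values, weights = values[keep], weights[keep]
    g = len(values)
    if g < 2:
        raise ValueError("need at least 2 non-empty blocks for the jackknife")
    n = weights.sum()
    theta = float(np.sum(weights * values) / n)
    theta_del = (n * theta - weights * values) / (n - weights)
    h = n / weights
    tau = h * theta - (h - 1.0) * theta_del
    theta_j = g * theta - float(np.sum((1.0 - weights / n) * theta_del))
    var = float(np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g)
    return theta, np.sqrt(var)


def _block_ids(g: GenotypeMatrix, block_bp: int) -> np.ndarray:
    """Contiguous block index per site, anchored at position 1 per chromosome."""
    ids = np.empty(g.n_sites, dtype=np.int64)
    offset = 0
    for ch in dict.fromkeys(g.chrom):
        sel = np.flatnonzero(g.chrom == ch)
        local = (g.pos[sel] - 1) // block_bp
        # compress to consecutive ids so empty blocks don't appear
        uniq, inv = np.unique(local, return_inverse=True)
        ids[sel] = offset + inv
        offset += len(uniq)
    return ids


def _site_contributions(kind: str, site_stats: dict, pops):
    p = {pop: site_stats[pop]["p"] for pop in pops}
    v = {pop: site_stats[pop]["var_p"] for pop in pops}
    with np.errstate(invalid="ignore"):
        if kind == "f2":
            a, b = pops
            vals = (p[a] - p[b]) ** 2 - v[a] - v[b]
        elif kind == "f3":
            c, a, b = pops
            vals = (p[c] - p[a]) * (p[c] - p[b]) - v[c]
        elif kind == "f4":
            a, b, c, d = pops
            vals = (p[a] - p[b]) * (p[c] - p[d])
        else:
            raise ValueError(f"unknown statistic kind {kind!r}")
    ok = np.ones(len(vals), dtype=bool)
    for pop in pops:
        # complete-case within the statistic: >=2 called diploids per pop
        ok &= site_stats[pop]["n_ind"] >= 2
    ok &= np.isfinite(vals)
    return np.where(ok, vals, np.nan), ok


def f_statistic(
    g: GenotypeMatrix,
    assignment: dict[str, str],
    kind: str,
    pops: tuple[str, ...],
    block_bp: int = 2_000_000,
) -> FStatResult:
    """Compute an f-statistic with block-jackknife SE and Z score.

    ``pops`` is the ordered population tuple: (A, B) for f2, (C, A, B) for
    f3 with C the target, (A, B, C, D) for f4.  Sites are used when every
    involved population has at least two called allele copies
    (complete-case within the statistic, not globally).
    """
    expect = {"f2": 2, "f3": 3, "f4": 4}
    if kind not in expect:
        raise ValueError(f"unknown statistic kind {kind!r}")
    if len(pops) != expect[kind]:
        raise ValueError(f"{kind} needs {expect[kind]} populations, got {len(pops)}")
    sub = {s: p for s, p in assignment.items() if p in pops and s in set(g.samples)}
    site_stats = pop_site_stats(g, sub)
    vals, ok = _site_contributions(kind, site_stats, pops)
    if ok.sum() == 0:
        raise ValueError("no sites with complete coverage in the involved populations")
    blocks = _block_ids(g, block_bp)
    uniq = np.unique(blocks[ok])
    means = np.array([np.nanmean(vals[(blocks == b) & ok]) for b in uniq])
    wts = np.array([((blocks == b) & ok).sum() for b in uniq], dtype=float)
    est, se = weighted_block_jackknife(means, wts)
    z = est / se if se > 0 else (0.0 if est == 0 else np.inf * np.sign(est))
    return FStatResult(
        kind=kind,
        pops=tuple(pops),
        estimate=est,
        se=se,
        z=float(z),
        n_blocks=len(uniq),
        n_sites=int(ok.sum()),
        block_bp=block_bp,
    )


def classify_significance(r: FStatResult, z_threshold: float = 3.0) -> str:
    """Three-way call: significant_positive / significant_negative / non_significant.

    Uses |Z| > z_threshold (strictly greater), the conventional cutoff.
    A zero SE with a nonzero estimate is flagged degenerate.
    """
    if r.se == 0 and r.estimate != 0:
        raise ValueError("degenerate result: SE = 0 with nonzero estimate")
    if r.z > z_threshold:
        return "significant_positive"
    if r.z < -z_threshold:
        return "significant_negative"
    return "non_significant"


def admixture_f3_scan(
    g: GenotypeMatrix,
    assignment: dict[str, str],
    target: str,
    sources: list[str] | None = None,
    block_bp: int = 2_000_000,
) -> pd.DataFrame:
    """f3(target; A, B) for every unordered source pair.

    A significantly negative value (Z < -3) flags the target as admixed
    between the two sources.
    """
    if sources is None:
        sources = sorted(set(assignment.values()) - {target})
    if target in sources:
        raise ValueError("target must not be among the sources")
    if len(sources) < 2:
        raise ValueError("need at least two source populations")
    rows = []
    for a, b in combinations(sources, 2):
        r = f_statistic(g, assignment, "f3", (target, a, b), block_bp=block_bp)
        rows.append(
            dict(
                target=target, source_a=a, source_b=b,
                estimate=r.estimate, se=r.se, z=r.z,
                n_blocks=r.n_blocks, n_sites=r.n_sites,
                significant_negative=classify_significance(r) == "significant_negative",
            )
        )
    return pd.DataFrame(rows)
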