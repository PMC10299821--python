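"""Windowed nucleotide diversity, absolute/relative divergence and LD decay.

pi and dxy are computed as ratios of sums ("count all mismatching allele
pairs, divide by all compared allele pairs"), never as averages of per-site
ratios, so that sites with missing data are weighted by the information
they actually carry and invariant sites enter the denominator.  This is
the estimator popularized by pixy and is the only unbiased choice when
genotype matrices contain missing calls and invariant sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genotypes import GenotypeMatrix

__all__ = [
    "WindowStats",
    "LDDecayCurve",
    "pop_allele_counts",
    "pop_site_stats",
    "window_pi_dxy",
    "fst",
    "hudson_components",
    "weir_cockerham_components",
    "ld_decay",
]


# ----------------------------------------------------------------------
def pop_allele_counts(g: GenotypeMatrix, assignment: dict[str, str]):
    """Per-population (alt count, total called alleles) arrays per site."""
    pops = sorted(set(assignment.values()))
    out = {}
    for pop in pops:
        idx = [i for i, s in enumerate(g.samples) if assignment.get(s) == pop]
        if not idx:
            raise ValueError(f"population {pop} has no samples")
        out[pop] = g.allele_counts(sample_idx=np.array(idx))
    return out


def pop_site_stats(g: GenotypeMatrix, assignment: dict[str, str]):
    """Per-population per-site frequency statistics.

    Returns ``pop -> dict`` with arrays ``p`` (alt frequency), ``n_alleles``
    (called allele copies), ``n_ind`` (called diploids), ``var_p`` (estimated
    sampling variance of p, from the unbiased dosage variance s^2/(4N) —
    valid under arbitrary inbreeding, equal to p q / n in expectation for
    outbred samples) and ``het_obs`` (observed heterozygote fraction).
    Sites with fewer than 2 called individuals carry NaN throughout.
    """
    pops = sorted(set(assignment.values()))
    out = {}
    for pop in pops:
        idx = np.array([i for i, s in enumerate(g.samples) if assignment.get(s) == pop])
        if len(idx) == 0:
            raise ValueError(f"population {pop} has no samples")
        calls = g.calls[:, idx]
        obs = calls != -1
        n_ind = obs.sum(axis=1)
        d = np.where(obs, calls, 0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            mean_d = d.sum(axis=1) / n_ind
            ss = ((d - mean_d[:, None]) ** 2 * obs).sum(axis=1)
            var_d = ss / (n_ind - 1)
            p = mean_d / 2.0
            var_p = var_d / (4.0 * n_ind)
            het = ((calls == 1) & obs).sum(axis=1) / n_ind
        bad = n_ind < 2
        for arr in (p, var_p, het):
            arr[bad] = np.nan
        out[pop] = dict(
            p=p,
            n_alleles=2 * n_ind.astype(np.int64),
            n_ind=n_ind.astype(np.int64),
            var_p=var_p,
            het_obs=het,
        )
    return out


def _pi_terms(alt: np.ndarray, tot: np.ndarray):
    """Within-population mismatch and comparison counts per site."""
    num = alt * (tot - alt)
    den = tot * (tot - 1) // 2
    return num.astype(float), den.astype(float)


def _dxy_terms(alt_a, tot_a, alt_b, tot_b):
    num = alt_a * (tot_b - alt_b) + alt_b * (tot_a - alt_a)
    den = tot_a * tot_b
    return num.astype(float), den.astype(float)


@dataclass
class WindowStats:
    """Windowed diversity/differentiation records.

    ``table`` columns: chrom, start, end (half-open bp window), stat
    (pi|dxy|fst), pops ("A" or "A|B"), value, n_sites, n_comparisons.
    Values are NaN when a window holds no compared allele pairs.
    """

    window_bp: int
    table: pd.DataFrame

    def value(self, stat: str, pops: str) -> pd.DataFrame:
        t = self.table
        return t[(t["stat"] == stat) & (t["pops"] == pops)].reset_index(drop=True)

    def global_value(self, stat: str, pops: str) -> float:
        """Ratio-of-sums aggregate of a statistic over all windows."""
        t = self.value(stat, pops)
        den = t["denominator"].sum()
        return float(t["numerator"].sum() / den) if den > 0 else float("nan")


def _windows_of(g: GenotypeMatrix, window_bp: int):
    """Yield (chrom, start, site-index array) for half-open windows from 1."""
    for ch in dict.fromkeys(g.chrom):
        sel = np.flatnonzero(g.chrom == ch)
        win_id = (g.pos[sel] - 1) // window_bp
        for w in np.unique(win_id):
            yield ch, int(w * window_bp + 1), sel[win_id == w]


def window_pi_dxy(
    g: GenotypeMatrix,
    assignment: dict[str, str],
    window_bp: int = 10_000,
    warn_no_invariant: bool = True,
) -> WindowStats:
    """Windowed pi and dxy over all sites, invariant sites included.

    pi(pop) = (sum over sites of mismatching within-population allele
    pairs) / (sum of compared pairs); dxy analogous with between-population
    pairs.  Windows are [start, start + window_bp) anchored at position 1.
    """
    if warn_no_invariant and g.is_variant.all() and g.n_sites > 0:
        warnings.warn(
            "no invariant sites present: pi and dxy are upwardly biased "
            "(denominator counts variant sites only)"
        )
    counts = pop_allele_counts(g, assignment)
    pops = sorted(counts)
    rows = []
    for ch, start, idx in _windows_of(g, window_bp):
        end = start + window_bp
        for pop in pops:
            alt, tot = counts[pop]
            num, den = _pi_terms(alt[idx], tot[idx])
            used = den > 0
            rows.append(
                dict(
                    chrom=ch, start=start, end=end, stat="pi", pops=pop,
                    numerator=num[used].sum(), denominator=den[used].sum(),
                    value=num[used].sum() / den[used].sum() if used.any() else np.nan,
                    n_sites=int(used.sum()), n_comparisons=den[used].sum(),
                )
            )
        for i, pa in enumerate(pops):
            for pb in pops[i + 1 :]:
                alt_a, tot_a = counts[pa]
                alt_b, tot_b = counts[pb]
                num, den = _dxy_terms(alt_a[idx], tot_a[idx], alt_b[idx], tot_b[idx])
                used = den > 0
                rows.append(
                    dict(
                        chrom=ch, start=start, end=end, stat="dxy", pops=f"{pa}|{pb}",
                        numerator=num[used].sum(), denominator=den[used].sum(),
                        value=num[used].sum() / den[used].sum() if used.any() else np.nan,
                        n_sites=int(used.sum()), n_comparisons=den[used].sum(),
                    )
                )
    return WindowStats(window_bp=window_bp, table=pd.DataFrame(rows))


# ----------------------------------------------------------------------
def hudson_components(stats_a: dict, stats_b: dict):
    """Per-site Hudson FST numerator/denominator with sample-size correction.

    num = (p1 - p2)^2 - Var(p1) - Var(p2)
    den = p1 q2 + p2 q1

    The sampling-variance terms come from :func:`pop_site_stats` (dosage
    variance), which keeps the numerator unbiased under inbreeding; for
    outbred samples they equal the familiar p q / (n - 1) form in
    expectation.  Sites with <2 called individuals in either population
    are NaN.
    """
    p1, p2 = stats_a["p"], stats_b["p"]
    num = (p1 - p2) ** 2 - stats_a["var_p"] - stats_b["var_p"]
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def weir_cockerham_components(site_stats: dict):
    """Per-site Weir–Cockerham (1984) theta components for r populations.

    ``site_stats`` is the output of :func:`pop_site_stats`.  Returns the
    numerator ``a`` and denominator ``a + b + c`` arrays; their ratio of
    sums is the multi-population theta.
    """
    pops = list(site_stats)
    r = len(pops)
    n_i = np.stack([site_stats[p]["n_ind"].astype(float) for p in pops])
    p_i = np.stack([site_stats[p]["p"] for p in pops])
    h_i = np.stack([site_stats[p]["het_obs"] for p in pops])
    valid = (n_i > 0).all(axis=0)
    n_bar = n_i.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
    bad = ~valid | (n_bar <= 1) | ~np.isfinite(n_c) | (n_c <= 0)
    a = np.where(bad, np.nan, a)
    tot = np.where(bad, np.nan, a + b + c)
    return a, tot


def fst(
    g: GenotypeMatrix,
    assignment: dict[str, str],
    pop_a: str | None = None,
    pop_b: str | None = None,
    mode: str = "global",
    window_bp: int = 10_000,
    estimator: str = "hudson",
):
    """FST between two populations (Hudson default, Weir–Cockerham by flag).

    ``mode`` is ``global`` (one ratio-of-sums value), ``windowed`` (a
    WindowStats-style table) or ``per_site`` (per-SNP values, used for the
    neutral-distribution tails in the QST comparison).  Negative per-site
    numerators are retained before summing.
    """
    if pop_a is None or pop_b is None:
        pops = sorted(set(assignment.values()))
        if len(pops) != 2:
            raise ValueError("specify pop_a and pop_b when more than two groups")
        pop_a, pop_b = pops
    sub = {s: p for s, p in assignment.items() if p in (pop_a, pop_b) and s in set(g.samples)}
    site_stats = pop_site_stats(g, sub)
    if estimator == "hudson":
        num, den = hudson_components(site_stats[pop_a], site_stats[pop_b])
    elif estimator == "weir_cockerham":
        num, den = weir_cockerham_components(site_stats)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    ok = np.isfinite(num) & np.isfinite(den)
    if mode == "global":
        if den[ok].sum() <= 0:
            return float("nan")
        return float(num[ok].sum() / den[ok].sum())
    if mode == "per_site":
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(ok & (den != 0), num / den, np.nan)
        return vals
    if mode == "windowed":
        rows = []
        for ch, start, idx in _windows_of(g, window_bp):
            sel = idx[ok[idx]]
            d = den[sel].sum()
            rows.append(
                dict(
                    chrom=ch, start=start, end=start + window_bp, stat="fst",
                    pops=f"{pop_a}|{pop_b}",
                    numerator=num[sel].sum(), denominator=d,
                    value=num[sel].sum() / d if d > 0 else np.nan,
                    n_sites=int(len(sel)), n_comparisons=float(d),
                )
            )
        return WindowStats(window_bp=window_bp, table=pd.DataFrame(rows))
    raise ValueError(f"unknown mode {mode!r}")


# ----------------------------------------------------------------------
@dataclass
class LDDecayCurve:
    """Binned r^2 versus physical distance with a smoothed curve.

    ``decay_length`` is the length-scale lambda of the exponential model
    r^2(d) = a * exp(-2 d / lambda) + b fitted to the binned means (the
    natural estimator of a latent correlation length); ``half_decay_bp``
    is the distance where the smoothed curve first falls halfway from its
    maximum to its asymptote.
    """

    bin_centers: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    smoothed: np.ndarray
    half_decay_bp: float
    decay_length: float
    fit_params: dict = field(default_factory=dict)


def ld_decay(
    g: GenotypeMatrix,
    max_dist_bp: int = 300_000,
    bin_width: int = 10_000,
    loess_span: float = 0.3,
    sample_idx=None,
) -> LDDecayCurve:
    """LD decay curve from all intra-chromosomal SNP pairs within range.

    r^2 is the squared Pearson correlation of mean-imputed dosages.
    """
    gv = g.variant_only()
    dos = gv.dosages_imputed(sample_idx=sample_idx)
    dists, r2s = [], []
    for ch in dict.fromkeys(gv.chrom):
        sel = np.flatnonzero(gv.chrom == ch)
        if len(sel) < 2:
            continue
        pos = gv.pos[sel]
        d = dos[sel]
        d0 = d - d.mean(axis=1, keepdims=True)
        sd = d0.std(axis=1)
        for i in range(len(sel)):
            if sd[i] == 0:
                continue
            j_hi = np.searchsorted(pos, pos[i] + max_dist_bp, side="right")
            js = np.arange(i + 1, j_hi)
            js = js[sd[js] > 0]
            if len(js) == 0:
                continue
            r = (d0[js] @ d0[i]) / (d.shape[1] * sd[js] * sd[i])
            dists.append(pos[js] - pos[i])
            r2s.append(r * r)
    if not dists:
        raise ValueError("no SNP pairs within max_dist_bp")
    dist = np.concatenate(dists).astype(float)
    r2 = np.concatenate(r2s)

    edges = np.arange(0, max_dist_bp + bin_width, bin_width)
    which = np.clip(np.digitize(dist, edges) - 1, 0, len(edges) - 2)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mean_r2 = np.full(len(centers), np.nan)
    n_pairs = np.zeros(len(centers), dtype=int)
    for b in range(len(centers)):
        m = which == b
        n_pairs[b] = m.sum()
        if n_pairs[b]:
            mean_r2[b] = r2[m].mean()
    okb = n_pairs > 0
    sm = np.full(len(centers), np.nan)
    if okb.sum() >= 3:
        fitted = lowess(
            mean_r2[okb], centers[okb], frac=loess_span, return_sorted=False
        )
        sm[okb] = fitted
    else:
        sm[okb] = mean_r2[okb]

    # half-decay distance of the smoothed curve
    sv = sm[okb]
    cv = centers[okb]
    top = np.nanmax(sv)
    asym = sv[-1]
    half = asym + 0.5 * (top - asym)
    below = np.flatnonzero(sv <= half)
    half_decay = float(cv[below[0]]) if len(below) else float(cv[-1])

    # exponential length-scale fit: r2(d) = a exp(-2 d / lam) + floor, with
    # the floor pinned at the finite-sample independence level 1/(n-1) so a
    # flat noise tail cannot inflate lam.  Pairs-per-bin weights, then one
    # refit excluding the near field (d < 0.4 lam), where threshold
    # correlations saturate and distort the exponential shape.
    n_samp = dos.shape[1]
    floor = 1.0 / max(n_samp - 1, 1)

    def model(d, a, lam):
        return a * np.exp(-2.0 * d / lam) + floor

    try:
        mv = mean_r2[okb]
        wv = n_pairs[okb].astype(float)
        p0 = (max(float(np.nanmax(mv)) - floor, 1e-3), max(half_decay, bin_width))
        bounds = ([0.0, 1.0], [1.0, 50.0 * max_dist_bp])
        popt, _ = curve_fit(model, cv, mv, p0=p0, sigma=1.0 / np.sqrt(wv),
                            bounds=bounds, maxfev=20_000)
        far = cv >= 0.4 * popt[1]
        if far.sum() >= 4:
            popt, _ = curve_fit(model, cv[far], mv[far], p0=tuple(popt),
                                sigma=1.0 / np.sqrt(wv[far]), bounds=bounds,
                                maxfev=20_000)
        decay_length = float(popt[1])
        fit = {"a": float(popt[0]), "lambda": float(popt[1]), "floor": floor}
    except Exception:  # fit can fail on flat curves; fall back to half decay
        decay_length = half_decay
        fit = {}
    return LDDecayCurve(
        bin_centers=centers,
        mean_r2=mean_r2,
        n_pairs=n_pairs,
        smoothed=sm,
        half_decay_bp=half_decay,
        decay_length=decay_length,
        fit_params=fit,
    )
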