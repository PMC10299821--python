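"""Great-circle geography, Mantel isolation-by-distance tests and spatial
gradient regressions.

Isolation by distance (IBD) — a positive correlation between pairwise
genetic and geographic distance — accumulates only in populations that
have occupied a region long enough for local differentiation; a recently
expanded population shows little or none.  The Mantel test quantifies it
with a permutation null that respects the non-independence of distance
matrix entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "haversine_matrix",
    "MantelResult",
    "mantel_test",
    "GradientResult",
    "gradient_regression",
    "diversity_gradient",
]


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def haversine_matrix(lon, lat) -> np.ndarray:
    """Symmetric great-circle distance matrix (km) for coordinate arrays."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range (lat in [-90,90], lon in [-180,180])")
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(d, 0.0)
    return d


# ----------------------------------------------------------------------
@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str


def _lower(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(len(m), k=-1)
    return m[i, j]


def mantel_test(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = 1000,
    tail: str = "one_sided_positive",
    seed: int | None = None,
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel correlation between two distance matrices with permutation p.

    r is the Pearson correlation of the lower-triangle entries; the null is
    generated by jointly permuting rows/columns of ``d2``.  The p-value uses
    the (1 + exceedances) / (n_perm + 1) convention; in ``exhaustive`` mode
    every permutation (identity included) is enumerated and
    p = exceedances / n!, which is exact for small n.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    n = len(d1)
    if d1.shape != (n, n) or d2.shape != (n, n):
        raise ValueError("distance matrices must be square and matched")
    if n < 4:
        raise ValueError("need at least 4 items")
    v1 = _lower(d1)
    if np.std(v1) == 0 or np.std(_lower(d2)) == 0:
        raise ValueError("constant distance matrix: correlation undefined")

    def corr(perm) -> float:
        m = d2[np.ix_(perm, perm)]
        return float(np.corrcoef(v1, _lower(m))[0, 1])

    r_obs = corr(np.arange(n))

    def extreme(r_p: float) -> bool:
        if tail == "one_sided_positive":
            return r_p >= r_obs - 1e-12
        if tail == "one_sided_negative":
            return r_p <= r_obs + 1e-12
        return abs(r_p) >= abs(r_obs) - 1e-12

    if exhaustive:
        perms = list(permutations(range(n)))
        hits = sum(extreme(corr(np.array(p))) for p in perms)
        return MantelResult(r=r_obs, p=hits / len(perms), n_perm=len(perms), tail=tail)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if extreme(corr(perm)):
            hits += 1
    return MantelResult(r=r_obs, p=(1 + hits) / (n_perm + 1), n_perm=n_perm, tail=tail)


# ----------------------------------------------------------------------
@dataclass
class GradientResult:
    slope: float
    intercept: float
    n: int
    r: float
    p: float
    description: str = ""


def gradient_regression(
    occurrences,
    raster,
    group_a: str,
    group_b: str | None = None,
    origin: tuple[float, float] | None = None,
) -> GradientResult:
    """OLS slope of a raster variable on great-circle distance from a group.

    Distances (km) are measured from ``origin`` (default: the unweighted
    coordinate centroid of ``group_a``) to every occurrence of the chosen
    group pair; the slope has units of the raster variable per km, e.g. a
    change in annual precipitation per kilometer along an expansion route.
    """
    occ = occurrences
    if group_b is None:
        sel = occ
    else:
        sel = occ[occ["group"].isin([group_a, group_b])]
    if len(sel) < 3:
        raise ValueError("need at least 3 occurrences")
    if origin is None:
        a = occ[occ["group"] == group_a]
        origin = (float(a["lon"].mean()), float(a["lat"].mean()))
    dist = haversine_km(origin[0], origin[1], sel["lon"].to_numpy(float), sel["lat"].to_numpy(float))
    vals = np.array([raster.value_at(lo, la) for lo, la in zip(sel["lon"], sel["lat"])])
    if np.ptp(dist) == 0:
        raise ValueError("no spread in distances")
    res = stats.linregress(dist, vals)
    return GradientResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=len(sel),
        r=float(res.rvalue),
        p=float(res.pvalue),
        description=f"{raster.name} on km from centroid of {group_a}"
        + (f" toward {group_b}" if group_b else ""),
    )


def diversity_gradient(pi_values, longitudes, description: str = "pi on longitude") -> GradientResult:
    """OLS of per-subpopulation nucleotide diversity on longitude.

    A positive slope means diversity increases eastward, the signature of a
    westward serial-founder expansion within the group.
    """
    pi_values = np.asarray(pi_values, dtype=float)
    longitudes = np.asarray(longitudes, dtype=float)
    if len(pi_values) < 3:
        raise ValueError("need at least 3 subpopulation points")
    if np.ptp(pi_values) == 0:
        return GradientResult(0.0, float(pi_values[0]), len(pi_values), 0.0, 1.0, description)
    res = stats.linregress(longitudes, pi_values)
    return GradientResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=len(pi_values),
        r=float(res.rvalue),
        p=float(res.pvalue),
        description=description,
    )
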