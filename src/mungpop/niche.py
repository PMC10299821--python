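"""Climatic-niche analyses: raster handling, variable decorrelation,
climate-space PCA/MANOVA, Gaussian-envelope suitability surfaces and
Schoener's D niche overlap.

The suitability model is a Gaussian envelope in climate space
(``exp(-Mahalanobis^2 / 2)`` around the group's climate mean with a
ridge-regularized covariance).  It is a deterministic, transparent niche
model; the surface container also accepts externally produced suitability
grids, so grids from any other niche model can be dropped in for the
overlap statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClimateRaster",
    "SuitabilitySurface",
    "read_ascii_grid",
    "extract_climate",
    "decorrelate_variables",
    "climate_pca_manova",
    "suitability_surface",
    "schoeners_d",
]


@dataclass
class ClimateRaster:
    """A rectangular lon/lat grid of one environmental variable.

    ``values`` rows are ordered north -> south (row 0 is the northernmost),
    matching the ESRI ASCII grid convention.  ``xll``/``yll`` give the
    lower-left corner of the grid (edge, not cell center).
    """

    name: str
    values: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; raises if outside."""
        col = int(np.floor((lon - self.xll) / self.cellsize))
        row_from_bottom = int(np.floor((lat - self.yll) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        if not (0 <= col < self.ncols and 0 <= row < self.nrows):
            raise ValueError(f"point ({lon}, {lat}) outside raster extent")
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of all cell centers, aligned with ``values``."""
        lons = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        lats = self.yll + (np.arange(self.nrows)[::-1] + 0.5) * self.cellsize
        return np.meshgrid(lons, lats)

    def value_at(self, lon: float, lat: float) -> float:
        r, c = self.cell_index(lon, lat)
        return float(self.values[r, c])

    def write_ascii(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xll!r}\n")
            fh.write(f"yllcorner {self.yll!r}\n")
            fh.write(f"cellsize {self.cellsize!r}\n")
            fh.write(f"NODATA_value {self.nodata!r}\n")
            for row in self.values:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str, name: str | None = None) -> ClimateRaster:
    """Read an ESRI ASCII grid (ncols/nrows/xllcorner/... header)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid body does not match declared nrows/ncols")
    return ClimateRaster(
        name=name or path,
        values=values,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


# ----------------------------------------------------------------------
def extract_climate(
    occurrences: pd.DataFrame, rasters: dict[str, ClimateRaster]
) -> pd.DataFrame:
    """Nearest-cell climate lookup for each occurrence point.

    ``occurrences`` needs ``lon``/``lat`` columns; other columns are carried
    through.  Points falling on a nodata cell in any raster get
    ``valid=False`` and are meant to be excluded downstream.
    """
    out = occurrences.reset_index(drop=True).copy()
    valid = np.ones(len(out), dtype=bool)
    for name, ras in rasters.items():
        vals = np.empty(len(out))
        for i, (lon, lat) in enumerate(zip(out["lon"], out["lat"])):
            v = ras.value_at(float(lon), float(lat))
            vals[i] = v
            if v == ras.nodata:
                valid[i] = False
        out[name] = vals
    out["valid"] = valid
    return out


def decorrelate_variables(
    climate: pd.DataFrame,
    variables: list[str] | None = None,
    r_threshold: float = 0.8,
    verbose: bool = False,
) -> list[str]:
    """Greedy removal of highly correlated climate variables.

    Variables are scanned in input (column) order; whenever a pair exceeds
    ``|r| > r_threshold`` the later-listed variable is dropped.  Constant
    variables (undefined correlation) are dropped with a warning.
    """
    if variables is None:
        variables = [c for c in climate.columns if c not in ("id", "group", "lon", "lat", "valid")]
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    retained: list[str] = []
    dropped: list[tuple[str, str]] = []
    for var in variables:
        x = climate[var].to_numpy(float)
        if np.std(x) == 0:
            import warnings

            warnings.warn(f"variable {var} is constant; dropped")
            continue
        clash = None
        for kept in retained:
            r = np.corrcoef(climate[kept].to_numpy(float), x)[0, 1]
            if abs(r) > r_threshold:
                clash = kept
                break
        if clash is None:
            retained.append(var)
        else:
            dropped.append((clash, var))
    if verbose and dropped:
        for kept, var in dropped:
            print(f"decorrelate: dropped {var} (|r| > {r_threshold} with {kept})")
    return retained


# ----------------------------------------------------------------------
def wilks_lambda(x: np.ndarray, groups: np.ndarray) -> tuple[float, float, tuple, float]:
    """One-way MANOVA via Wilks' Lambda with Rao's F approximation.

    Returns (lambda, F, (df1, df2), p).
    """
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    n, p = x.shape
    g = len(labels)
    if g < 2:
        raise ValueError("need at least two groups")
    grand = x.mean(axis=0)
    E = np.zeros((p, p))
    H = np.zeros((p, p))
    for lab in labels:
        xi = x[groups == lab]
        mi = xi.mean(axis=0)
        d = xi - mi
        E += d.T @ d
        dm = (mi - grand)[:, None]
        H += len(xi) * (dm @ dm.T)
    det_e = np.linalg.det(E)
    if det_e <= 0:
        raise np.linalg.LinAlgError("singular within-group covariance")
    lam = det_e / np.linalg.det(E + H)
    # Rao's F approximation
    vh = g - 1
    ve = n - g
    if p * p + vh * vh > 5:
        t = np.sqrt((p * p * vh * vh - 4) / (p * p + vh * vh - 5))
    else:
        t = 1.0
    df1 = p * vh
    df2 = (ve + vh - (p + vh + 1) / 2) * t - (p * vh - 2) / 2
    lam_t = lam ** (1.0 / t)
    f = (1 - lam_t) / lam_t * df2 / df1
    pval = float(stats.f.sf(f, df1, df2))
    return float(lam), float(f), (float(df1), float(df2)), pval


def climate_pca_manova(
    climate: pd.DataFrame, groups, variables: list[str] | None = None
) -> dict:
    """PCA on standardized climate variables plus a one-way MANOVA.

    Returns a dict with PCA scores/explained fractions and the MANOVA
    report (Wilks' Lambda, approximate F, degrees of freedom, p-value).
    """
    if variables is None:
        variables = [c for c in climate.columns if c not in ("id", "group", "lon", "lat", "valid")]
    x = climate[variables].to_numpy(float)
    groups = np.asarray(groups)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    scores = u * s
    explained = (s**2) / np.sum(s**2)
    lam, f, df, pval = wilks_lambda(x, groups)
    return {
        "scores": scores,
        "explained": explained,
        "loadings": vt.T,
        "wilks_lambda": lam,
        "F": f,
        "df": df,
        "p": pval,
    }


# ----------------------------------------------------------------------
@dataclass
class SuitabilitySurface:
    """Habitat-suitability grid aligned to a reference raster.

    ``raw`` holds envelope values in [0, 1]; ``prob`` is the same grid
    normalized to sum to 1 (nodata cells carry 0), the form Schoener's D
    operates on.
    """

    group: str
    raw: np.ndarray
    prob: np.ndarray
    xll: float
    yll: float
    cellsize: float

    def to_raster(self, normalized: bool = False) -> ClimateRaster:
        vals = self.prob if normalized else self.raw
        return ClimateRaster(
            name=f"suitability_{self.group}",
            values=vals,
            xll=self.xll,
            yll=self.yll,
            cellsize=self.cellsize,
        )

    @classmethod
    def from_raster(cls, ras: ClimateRaster, group: str = "") -> "SuitabilitySurface":
        raw = np.where(ras.values == ras.nodata, 0.0, ras.values)
        total = raw.sum()
        if total <= 0:
            raise ValueError("surface has no positive mass")
        return cls(
            group=group or ras.name,
            raw=raw,
            prob=raw / total,
            xll=ras.xll,
            yll=ras.yll,
            cellsize=ras.cellsize,
        )


def suitability_surface(
    group_climate: pd.DataFrame,
    rasters: dict[str, ClimateRaster],
    variables: list[str] | None = None,
    group: str = "",
    ridge: float = 1e-6,
) -> SuitabilitySurface:
    """Gaussian-envelope suitability from a group's occurrence climate.

    suitability(cell) = exp(-Mahalanobis^2(cell climate; mean, cov)/2) with
    the covariance ridge-regularized by ``ridge`` times the mean diagonal.
    The raw envelope is 1.0 where the cell climate equals the group mean.
    """
    if variables is None:
        variables = [c for c in group_climate.columns if c in rasters]
    if len(group_climate) < len(variables) + 1:
        raise ValueError("need more occurrences than climate variables")
    x = group_climate[variables].to_numpy(float)
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    cov = np.atleast_2d(cov)
    scale = max(np.trace(cov) / len(variables), 1e-12)
    cov = cov + ridge * scale * np.eye(len(variables))
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError("singular covariance after regularization") from exc
    ref = rasters[variables[0]]
    stack = np.stack([rasters[v].values for v in variables], axis=-1)
    nodata = np.zeros(ref.values.shape, dtype=bool)
    for v in variables:
        nodata |= rasters[v].values == rasters[v].nodata
    d = stack - mean
    maha2 = np.einsum("rci,ij,rcj->rc", d, prec, d)
    raw = np.exp(-0.5 * maha2)
    raw[nodata] = 0.0
    total = raw.sum()
    if total <= 0:
        raise ValueError("suitability surface has no positive mass")
    return SuitabilitySurface(
        group=group,
        raw=raw,
        prob=raw / total,
        xll=ref.xll,
        yll=ref.yll,
        cellsize=ref.cellsize,
    )


def schoeners_d(s1: SuitabilitySurface, s2: SuitabilitySurface) -> float:
    """Schoener's D niche overlap: 1 - sum|p1 - p2| / 2 over aligned grids.

    Ranges from 0 (disjoint niches) to 1 (identical niches); symmetric.
    """
    if s1.prob.shape != s2.prob.shape or (s1.xll, s1.yll, s1.cellsize) != (
        s2.xll,
        s2.yll,
        s2.cellsize,
    ):
        raise ValueError("suitability grids are not aligned")
    return float(1.0 - 0.5 * np.abs(s1.prob - s2.prob).sum())
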