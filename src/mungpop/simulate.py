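"""Synthetic data with analytically known ground truth.

Four generators cover the inputs of the analysis chain:

* allele frequencies evolved over an :class:`~mungpop.graphs.AdmixtureGraph`
  by Balding–Nichols Beta drift (closed-form f-statistic expectations);
* diploid genotypes with partial selfing (inbreeding coefficient f),
  distance-decaying LD via a Gaussian copula, and uniform missingness;
* climate landscapes with linear spatial gradients and niche-constrained
  occurrence points;
* trait tables with specified among-group / among-accession / additive
  polygenic / batch / residual variance components.

All randomness flows through a single integer seed per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix
from .graphs import AdmixtureGraph
from .geo import KM_PER_DEG
from .niche import ClimateRaster

__all__ = [
    "SimulationConfig",
    "TraitSimSpec",
    "simulate_graph_frequencies",
    "simulate_genotypes",
    "simulate_landscape",
    "simulate_traits",
    "default_chromosomes",
]


def default_chromosomes(n: int = 11, length_bp: int = 40_000_000) -> dict[str, int]:
    """Chromosome naming/length layout: 11 chromosomes by default."""
    return {f"chr{i + 1}": length_bp for i in range(n)}


@dataclass
class SimulationConfig:
    """Genotype-simulation settings.

    Attributes
    ----------
    n_sites : total number of sites, spread uniformly over chromosomes.
    chromosomes : name -> length (bp); default 11 chromosomes.
    sample_sizes : population -> number of diploid individuals.
    inbreeding : Wright's f in [0, 1]; genotype frequencies follow
        {p^2 + f p q, 2 p q (1 - f), q^2 + f p q}.  Partial selfing in a
        predominantly autogamous crop keeps f high (around 0.84).
    missing_rate : uniform no-call probability, at most 0.1.
    ld_decay_bp : latent-correlation length L; the Gaussian copula gives
        latent correlation exp(-d / L) between sites d bp apart.  May be a
        single float or a per-population mapping.
    seed : fully determines the output.
    """

    n_sites: int = 10_000
    chromosomes: dict[str, int] = field(default_factory=default_chromosomes)
    sample_sizes: dict[str, int] = field(default_factory=dict)
    inbreeding: float = 0.84
    missing_rate: float = 0.0
    ld_decay_bp: float | dict[str, float] = 50_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inbreeding <= 1.0:
            raise ValueError(f"inbreeding f outside [0,1]: {self.inbreeding}")
        if not 0.0 <= self.missing_rate <= 0.1:
            raise ValueError(f"missing rate outside [0,0.1]: {self.missing_rate}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")

    def decay_for(self, pop: str) -> float:
        if isinstance(self.ld_decay_bp, dict):
            return float(self.ld_decay_bp[pop])
        return float(self.ld_decay_bp)


# ----------------------------------------------------------------------
def simulate_graph_frequencies(
    graph: AdmixtureGraph, n_sites: int, seed: int | None = None
) -> pd.DataFrame:
    """Evolve per-site allele frequencies down an admixture graph.

    Root frequencies are uniform on the graph's ``root_freq`` interval.
    Each drift edge with parameter c draws the child frequency from a Beta
    distribution with mean p and variance c * p * (1 - p) (Balding–Nichols);
    admixture nodes mix their sources linearly.  Returns a DataFrame with
    one column per graph node (leaves included), one row per site.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = graph.root_freq
    freqs: dict[str, np.ndarray] = {graph.root: rng.uniform(lo, hi, size=n_sites)}
    for node in graph.topological_order():
        if node == graph.root:
            continue
        if node in graph.admixtures:
            a, b, alpha = graph.admixtures[node]
            freqs[node] = alpha * freqs[a] + (1.0 - alpha) * freqs[b]
        else:
            parent, c = graph.edges[node]
            p = freqs[parent]
            if c == 0.0:
                freqs[node] = p.copy()
            else:
                shape = (1.0 - c) / c
                a_par = np.maximum(p * shape, 1e-12)
                b_par = np.maximum((1.0 - p) * shape, 1e-12)
                child = rng.beta(a_par, b_par)
                # frequencies already fixed stay fixed
                child = np.where(p <= 0.0, 0.0, np.where(p >= 1.0, 1.0, child))
                freqs[node] = np.clip(child, 0.0, 1.0)
    return pd.DataFrame(freqs)


# ----------------------------------------------------------------------
def _site_positions(config: SimulationConfig, rng: np.random.Generator):
    """Uniformly spread sites over chromosomes; returns (chrom, pos) arrays."""
    names = list(config.chromosomes)
    lengths = np.array([config.chromosomes[c] for c in names], dtype=float)
    weights = lengths / lengths.sum()
    counts = rng.multinomial(config.n_sites, weights)
    chrom, pos = [], []
    for name, length, k in zip(names, lengths, counts):
        if k == 0:
            continue
        p = np.sort(rng.choice(int(length), size=k, replace=False)) + 1
        chrom.extend([name] * k)
        pos.extend(p.tolist())
    return np.array(chrom, dtype=object), np.array(pos, dtype=np.int64)


def _latent_paths(
    n_paths: int, pos: np.ndarray, decay_bp: float, rng: np.random.Generator
) -> np.ndarray:
    """AR(1) standard-normal paths with corr exp(-d/L) between sites.

    The exponential correlation makes the latent process Markov along the
    chromosome, so sequential generation is exact.
    """
    m = len(pos)
    z = np.empty((n_paths, m))
    eps = rng.standard_normal((n_paths, m))
    z[:, 0] = eps[:, 0]
    if m > 1:
        rho = np.exp(-np.diff(pos) / decay_bp)
        sig = np.sqrt(1.0 - rho**2)
        for i in range(1, m):
            z[:, i] = rho[i - 1] * z[:, i - 1] + sig[i - 1] * eps[:, i]
    return z


def simulate_genotypes(
    freqs: pd.DataFrame, config: SimulationConfig
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Draw diploid genotypes from per-population site frequencies.

    Each individual carries two allele copies per site; with probability f
    (the inbreeding coefficient) the two copies are identical by descent
    for the whole chromosome, which yields the single-site genotype law
    {p^2 + f p q, 2 p q (1 - f), q^2 + f p q}.  Alleles are thresholded
    latent AR(1) Gaussians, giving latent correlation exp(-d/L) between
    sites.  Missing calls are inserted uniformly at random.

    Returns the genotype matrix plus a sample -> population mapping.
    """
    pops = [p for p in config.sample_sizes if config.sample_sizes[p] > 0]
    missing_pops = [p for p in pops if p not in freqs.columns]
    if missing_pops:
        raise ValueError(f"populations without frequencies: {missing_pops}")
    if len(freqs) != config.n_sites:
        raise ValueError(
            f"frequency table has {len(freqs)} rows but config.n_sites={config.n_sites}"
        )
    rng = np.random.default_rng(config.seed)
    chrom, pos = _site_positions(config, rng)
    n_total = sum(config.sample_sizes[p] for p in pops)
    calls = np.empty((config.n_sites, n_total), dtype=np.int8)
    samples: list[str] = []
    groups: dict[str, str] = {}
    col = 0
    for pop in pops:
        n = config.sample_sizes[pop]
        names = [f"{pop}_{i:03d}" for i in range(n)]
        samples.extend(names)
        groups.update({s: pop for s in names})
        p_site = freqs[pop].to_numpy(float)
        thresh = stats.norm.ppf(np.clip(p_site, 0.0, 1.0))
        decay = config.decay_for(pop)
        pop_calls = np.empty((config.n_sites, n), dtype=np.int8)
        for ch in dict.fromkeys(chrom):
            sel = np.flatnonzero(chrom == ch)
            z = _latent_paths(2 * n, pos[sel], decay, rng)
            a1 = (z[0::2].T < thresh[sel][:, None]).astype(np.int8)
            a2 = (z[1::2].T < thresh[sel][:, None]).astype(np.int8)
            # identity-by-descent per site: the second copy duplicates the
            # first with probability f, giving the partial-selfing genotype
            # law while each copy keeps its own LD structure
            if config.inbreeding > 0:
                ibd = rng.random(a1.shape) < config.inbreeding
                a2 = np.where(ibd, a1, a2)
            pop_calls[sel] = a1 + a2
        calls[:, col : col + n] = pop_calls
        col += n
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING
    # site records: alleles named A (ref) / T (alt); sites where no alt
    # allele was observed carry an empty ALT list (invariant)
    observed = calls != MISSING
    alt_seen = (np.where(observed, calls, 0) > 0).any(axis=1)
    g = GenotypeMatrix(
        samples=samples,
        chrom=chrom,
        pos=pos,
        ref=["A"] * config.n_sites,
        alt=[["T"] if v else [] for v in alt_seen],
        calls=calls,
    )
    return g, groups


# ----------------------------------------------------------------------
def simulate_landscape(
    extent: tuple[float, float, float, float],
    cellsize: float,
    gradients: dict[str, dict],
    niches: dict[str, dict] | None = None,
    n_occurrences: int | dict[str, int] = 100,
    seed: int | None = None,
) -> tuple[dict[str, ClimateRaster], pd.DataFrame]:
    """Build gradient rasters and sample niche-constrained occurrences.

    Parameters
    ----------
    extent : (lon_min, lon_max, lat_min, lat_max) in degrees.
    cellsize : cell edge in degrees.
    gradients : variable -> dict with keys ``base`` (value at the west/south
        edge), ``slope_per_km`` (change per km), ``direction`` ("east" or
        "north") and optional ``noise_sd``.  East-west gradients are linear
        in along-parallel arc distance, so two cells d km apart on a
        parallel differ by exactly slope * d when noise is zero.
    niches : group -> {"centroid": {var: value}, "spread": {var: sd}};
        occurrences are drawn from cells with probability proportional to
        the group's Gaussian climate-space density at the cell.
    n_occurrences : per group (int applies to every group).

    Returns (rasters, occurrence table with id/group/lon/lat columns).
    """
    lon_min, lon_max, lat_min, lat_max = extent
    if lon_max <= lon_min or lat_max <= lat_min or cellsize <= 0:
        raise ValueError("empty extent or non-positive cell size")
    rng = np.random.default_rng(seed)
    ncols = int(round((lon_max - lon_min) / cellsize))
    nrows = int(round((lat_max - lat_min) / cellsize))
    if ncols < 1 or nrows < 1:
        raise ValueError("extent smaller than one cell")
    lon_c = lon_min + (np.arange(ncols) + 0.5) * cellsize
    lat_c = lat_min + (np.arange(nrows)[::-1] + 0.5) * cellsize  # north->south
    lon_g, lat_g = np.meshgrid(lon_c, lat_c)

    rasters: dict[str, ClimateRaster] = {}
    for name, spec in gradients.items():
        base = float(spec.get("base", 0.0))
        slope = float(spec.get("slope_per_km", 0.0))
        direction = spec.get("direction", "east")
        noise = float(spec.get("noise_sd", 0.0))
        if direction == "east":
            dist_km = KM_PER_DEG * np.cos(np.radians(lat_g)) * (lon_g - lon_min)
        elif direction == "north":
            dist_km = KM_PER_DEG * (lat_g - lat_min)
        else:
            raise ValueError(f"unknown gradient direction {direction!r}")
        vals = base + slope * dist_km
        if noise > 0:
            vals = vals + rng.normal(0.0, noise, size=vals.shape)
        rasters[name] = ClimateRaster(
            name=name, values=vals, xll=lon_min, yll=lat_min, cellsize=cellsize
        )

    rows = []
    if niches:
        var_names = list(gradients)
        stack = np.stack([rasters[v].values for v in var_names], axis=-1)
        for grp, spec in niches.items():
            n_occ = n_occurrences[grp] if isinstance(n_occurrences, dict) else n_occurrences
            if n_occ < 1:
                raise ValueError(f"zero occurrences requested for {grp}")
            cent = np.array([spec["centroid"][v] for v in var_names], dtype=float)
            spread = np.array([spec["spread"][v] for v in var_names], dtype=float)
            logw = -0.5 * (((stack - cent) / spread) ** 2).sum(axis=-1)
            w = np.exp(logw - logw.max()).ravel()
            w = w / w.sum()
            cells = rng.choice(len(w), size=n_occ, replace=True, p=w)
            r, c = np.unravel_index(cells, (nrows, ncols))
            for k in range(n_occ):
                rows.append(
                    {
                        "id": f"{grp}_{k:03d}",
                        "group": grp,
                        "lon": float(lon_g[r[k], c[k]]),
                        "lat": float(lat_g[r[k], c[k]]),
                    }
                )
    occurrences = pd.DataFrame(rows, columns=["id", "group", "lon", "lat"])
    return rasters, occurrences


# ----------------------------------------------------------------------
@dataclass
class TraitSimSpec:
    """Variance-component specification for trait simulation.

    Variances are on the trait scale (squared units): ``v_b`` among groups,
    ``v_fam`` among accessions within groups, ``v_aw`` additive polygenic
    (spread through the relationship matrix), ``v_batch`` and ``v_resid``.
    ``treatment_effect`` shifts the second treatment level;
    ``interaction`` optionally adds a per-group shift under that treatment.
    """

    group_means: dict[str, float]
    v_b: float = 0.0
    v_fam: float = 0.0
    v_aw: float = 0.0
    v_batch: float = 0.0
    v_resid: float = 1.0
    treatment_effect: float = 0.0
    interaction: dict[str, float] = field(default_factory=dict)
    treatments: tuple[str, ...] = ("control", "drought")
    n_batches: int = 2
    n_reps: int = 3
    trait: str = "trait"

    def __post_init__(self) -> None:
        for name in ("v_b", "v_fam", "v_aw", "v_batch", "v_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_batches < 1 or self.n_reps < 1 or not self.treatments:
            raise ValueError("design dimensions must be positive")


def simulate_traits(
    spec: TraitSimSpec,
    assignment: dict[str, str],
    relationship: np.ndarray | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a balanced trait table from a variance-component spec.

    value = group mean (+ N(0, v_b) group deviation) + accession deviation
    N(0, v_fam) + polygenic value MVN(0, v_aw * K) + batch effect
    N(0, v_batch) + treatment (+ interaction) shift + residual N(0, v_resid).

    ``assignment`` maps accession -> group (its order fixes the K rows).
    """
    rng = np.random.default_rng(seed)
    accessions = list(assignment)
    groups = sorted(set(assignment.values()))
    unknown = [g for g in set(assignment.values()) if g not in spec.group_means]
    if unknown:
        raise ValueError(f"groups without a specified mean: {unknown}")
    n_acc = len(accessions)
    if relationship is None:
        relationship = np.eye(n_acc)
    relationship = np.asarray(relationship, dtype=float)
    if relationship.shape != (n_acc, n_acc):
        raise ValueError("relationship matrix does not match the accession list")
    eigval = np.linalg.eigvalsh(relationship)
    if eigval.min() < -1e-8 * max(eigval.max(), 1.0):
        raise ValueError("relationship matrix is not positive semi-definite")

    g_dev = {g: rng.normal(0.0, np.sqrt(spec.v_b)) if spec.v_b > 0 else 0.0 for g in groups}
    fam = rng.normal(0.0, np.sqrt(spec.v_fam), size=n_acc) if spec.v_fam > 0 else np.zeros(n_acc)
    if spec.v_aw > 0:
        root = np.linalg.cholesky(
            relationship + 1e-10 * np.eye(n_acc) * max(eigval.max(), 1.0)
        )
        poly = np.sqrt(spec.v_aw) * (root @ rng.standard_normal(n_acc))
    else:
        poly = np.zeros(n_acc)
    batches = [f"batch{b + 1}" for b in range(spec.n_batches)]
    b_eff = (
        rng.normal(0.0, np.sqrt(spec.v_batch), size=spec.n_batches)
        if spec.v_batch > 0
        else np.zeros(spec.n_batches)
    )

    rows = []
    for ai, acc in enumerate(accessions):
        grp = assignment[acc]
        base = spec.group_means[grp] + g_dev[grp] + fam[ai] + poly[ai]
        for bi, batch in enumerate(batches):
            for ti, trt in enumerate(spec.treatments):
                shift = 0.0
                if ti > 0:
                    shift = spec.treatment_effect + spec.interaction.get(grp, 0.0)
                for rep in range(spec.n_reps):
                    val = base + b_eff[bi] + shift
                    if spec.v_resid > 0:
                        val += rng.normal(0.0, np.sqrt(spec.v_resid))
                    rows.append(
                        {
                            "accession": acc,
                            "group": grp,
                            "batch": batch,
                            "treatment": trt,
                            "replicate": rep + 1,
                            "trait": spec.trait,
                            "value": val,
                        }
                    )
    return pd.DataFrame(rows)
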