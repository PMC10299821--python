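"""Quantitative genetics: trait transforms, mixed-model ANOVA, variance
components, inbreeding, QST and the QST–FST divergent-selection test.

QST is the quantitative-trait analog of FST.  For a selfed-progeny design
in a partially selfing species it is computed as

    QST = V_B / (V_B + V_Fam)                               (equation 1)
    QST = (1 + f) V_B / ((1 + f) V_B + 2 V_AW)              (equation 2)

with V_B the among-group variance, V_Fam the among-accession-within-group
variance, V_AW the additive genetic variance within groups (from a kinship
mixed model) and f the inbreeding coefficient.  A trait whose QST exceeds
the upper tail of the per-SNP FST distribution is a candidate for
divergent selection among groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "VarianceComponents",
    "QstResult",
    "inverse_normal_transform",
    "estimate_inbreeding",
    "mixed_anova",
    "variance_components",
    "additive_variance_within",
    "qst",
    "qst_fst_compare",
    "tukey_groups",
]


# ----------------------------------------------------------------------
def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    x -> Phi^-1((rank - 3/8) / (n + 1/4)); ties receive average ranks.
    """
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 2:
        raise ValueError("all values equal: transform undefined")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.375) / (len(values) + 0.25))


# ----------------------------------------------------------------------
def estimate_inbreeding(g: GenotypeMatrix) -> tuple[np.ndarray, float]:
    """Method-of-moments inbreeding F per sample and the panel mean.

    F = (O_hom - E_hom) / (N - E_hom) where E_hom sums, over the sample's
    called polymorphic sites, the unbiased expected homozygosity
    1 - 2 p q n/(n - 1) from the panel allele frequencies.
    """
    alt, tot = g.allele_counts()
    poly = (alt > 0) & (alt < tot) & (tot >= 2)
    if not poly.any():
        raise ValueError("no polymorphic sites")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt[poly] / tot[poly]
        e_site = 1.0 - 2.0 * p * (1 - p) * tot[poly] / (tot[poly] - 1)
    calls = g.calls[poly]
    obs = calls != MISSING
    o_hom = ((calls == 0) | (calls == 2)) & obs
    n_called = obs.sum(axis=0)
    e_hom = (e_site[:, None] * obs).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (o_hom.sum(axis=0) - e_hom) / (n_called - e_hom)
    return f, float(np.nanmean(f))


# ----------------------------------------------------------------------
def _check_design(t: pd.DataFrame):
    for col in ("accession", "group", "batch", "treatment", "value"):
        if col not in t.columns:
            raise ValueError(f"trait table lacks column {col!r}")


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "ns"


def mixed_anova(t: pd.DataFrame) -> pd.DataFrame:
    """Mixed-model ANOVA for a treatment x group design with nested accessions.

    Treatment and genetic group are fixed; accessions (nested within
    groups) and batches are random.  With the balanced expected-mean-squares
    convention, the group effect is tested against accession-within-group
    and treatment / treatment x group against treatment x accession.
    Returns a table with df, SS, MS, F, p and significance stars.
    """
    _check_design(t)
    if t["group"].nunique() < 2 or t["treatment"].nunique() < 2:
        raise ValueError("need at least 2 groups and 2 treatments")
    counts = t.groupby(["treatment", "accession", "batch"], observed=True)["value"].count()
    if counts.nunique() > 1:
        warnings.warn("unbalanced design: expected-mean-squares F tests are approximate")
    y = t["value"].to_numpy(float)
    grand = y.mean()
    n_total = len(t)

    def cell_means(keys):
        return t.groupby(keys, observed=True)["value"].transform("mean")

    m_t = cell_means(["treatment"])
    m_g = cell_means(["group"])
    m_tg = cell_means(["treatment", "group"])
    m_a = cell_means(["accession"])
    m_ta = cell_means(["treatment", "accession"])
    m_b = cell_means(["batch"])

    ss_t = float(((m_t - grand) ** 2).sum())
    ss_g = float(((m_g - grand) ** 2).sum())
    ss_tg = float(((m_tg - m_t - m_g + grand) ** 2).sum())
    ss_a = float(((m_a - m_g) ** 2).sum())
    ss_ta = float(((m_ta - m_a - m_tg + m_g) ** 2).sum())
    ss_b = float(((m_b - grand) ** 2).sum())
    ss_tot = float(((y - grand) ** 2).sum())
    ss_e = max(ss_tot - ss_t - ss_g - ss_tg - ss_a - ss_ta - ss_b, 0.0)

    n_t = t["treatment"].nunique()
    n_g = t["group"].nunique()
    n_b = t["batch"].nunique()
    n_acc = t["accession"].nunique()
    df_t = n_t - 1
    df_g = n_g - 1
    df_tg = df_t * df_g
    df_a = n_acc - n_g
    df_ta = df_t * df_a
    df_b = n_b - 1
    df_e = n_total - 1 - df_t - df_g - df_tg - df_a - df_ta - df_b

    rows = []

    def add(source, ss, df, f=None, p=None):
        rows.append(
            dict(
                source=source, df=df, ss=ss, ms=ss / df if df > 0 else np.nan,
                F=f, p=p, sig=_stars(p) if p is not None else "",
            )
        )

    ms_a = ss_a / df_a if df_a > 0 else np.nan
    ms_ta = ss_ta / df_ta if df_ta > 0 else np.nan
    ms_e = ss_e / df_e if df_e > 0 else np.nan

    f_t = (ss_t / df_t) / ms_ta
    f_g = (ss_g / df_g) / ms_a
    f_tg = (ss_tg / df_tg) / ms_ta
    add("treatment", ss_t, df_t, f_t, float(stats.f.sf(f_t, df_t, df_ta)))
    add("group", ss_g, df_g, f_g, float(stats.f.sf(f_g, df_g, df_a)))
    add("treatment:group", ss_tg, df_tg, f_tg, float(stats.f.sf(f_tg, df_tg, df_ta)))
    add("accession(group)", ss_a, df_a)
    add("treatment:accession(group)", ss_ta, df_ta)
    add("batch", ss_b, df_b)
    add("residual", ss_e, df_e)
    return pd.DataFrame(rows)


def tukey_groups(t: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise group comparisons on accession means."""
    means = t.groupby(["group", "accession"], observed=True)["value"].mean().reset_index()
    groups = sorted(means["group"].unique())
    samples = [means.loc[means["group"] == g, "value"].to_numpy() for g in groups]
    res = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                dict(
                    group_a=groups[i], group_b=groups[j],
                    diff=float(np.mean(samples[i]) - np.mean(samples[j])),
                    p=float(res.pvalue[i, j]),
                    significant=bool(res.pvalue[i, j] < alpha),
                )
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
@dataclass
class VarianceComponents:
    """Variance decomposition of a trait table (all components >= 0)."""

    v_b: float
    v_fam: float
    v_batch: float
    v_resid: float
    v_aw: float | None = None
    method: str = "moments"
    truncated: list[str] = field(default_factory=list)


def variance_components(t: pd.DataFrame) -> VarianceComponents:
    """Balanced expected-mean-squares variance components.

    Random model: value = group + accession(group) + batch + residual,
    fitted to one treatment at a time (subset the table first).  Negative
    method-of-moments solutions are truncated to zero and flagged.
    """
    _check_design(t)
    if t["treatment"].nunique() > 1:
        raise ValueError("subset to a single treatment before decomposing variance")
    n_g = t["group"].nunique()
    n_b = t["batch"].nunique()
    n_acc = t["accession"].nunique()
    if n_g < 2 or n_acc < 2 * n_g:
        raise ValueError("need >=2 groups and >=2 accessions per group")
    reps = t.groupby(["accession", "batch"], observed=True)["value"].count()
    if reps.min() < 1 or (reps.nunique() > 1):
        warnings.warn("unbalanced design: using mean cell counts in the EMS solution")
    r = float(reps.mean())
    a = n_acc / n_g  # accessions per group (balanced)

    y = t["value"].to_numpy(float)
    grand = y.mean()
    m_g = t.groupby("group", observed=True)["value"].transform("mean")
    m_a = t.groupby("accession", observed=True)["value"].transform("mean")
    m_b = t.groupby("batch", observed=True)["value"].transform("mean")
    ss_g = float(((m_g - grand) ** 2).sum())
    ss_a = float(((m_a - m_g) ** 2).sum())
    ss_b = float(((m_b - grand) ** 2).sum()) if n_b > 1 else 0.0
    ss_tot = float(((y - grand) ** 2).sum())
    ss_e = max(ss_tot - ss_g - ss_a - ss_b, 0.0)
    df_g = n_g - 1
    df_a = n_acc - n_g
    df_b = n_b - 1
    df_e = len(t) - 1 - df_g - df_a - df_b
    if df_e <= 0:
        raise ValueError("unreplicated design: residual variance inseparable")
    ms_g, ms_a_, ms_e = ss_g / df_g, ss_a / df_a, ss_e / df_e

    truncated = []
    v_resid = ms_e
    v_fam = (ms_a_ - ms_e) / (n_b * r)
    v_b = (ms_g - ms_a_) / (a * n_b * r)
    v_batch = (ss_b / df_b - ms_e) / (n_g * a * r) if n_b > 1 else 0.0
    out = {}
    for name, v in (("v_b", v_b), ("v_fam", v_fam), ("v_batch", v_batch), ("v_resid", v_resid)):
        if v < 0:
            truncated.append(name)
            v = 0.0
        out[name] = float(v)
    return VarianceComponents(**out, method="moments", truncated=truncated)


# ----------------------------------------------------------------------
def additive_variance_within(
    t: pd.DataFrame,
    relationship: np.ndarray,
    accessions: list[str] | None = None,
) -> tuple[float, float]:
    """REML estimate of the additive genetic variance within groups (V_AW).

    Single-random-effect mixed model: value = group (fixed) [+ batch fixed
    when present] + polygenic effect with covariance V_AW * K + residual.
    Fitted by restricted maximum likelihood on the spectral decomposition
    of Z K Z', profiling the total variance and optimizing the heritability
    ratio.  Returns (V_AW, V_resid).
    """
    _check_design(t)
    if accessions is None:
        accessions = list(dict.fromkeys(t["accession"]))
    k = np.asarray(relationship, dtype=float)
    if k.shape != (len(accessions), len(accessions)):
        raise ValueError("relationship matrix does not match accession list")
    eigval = np.linalg.eigvalsh(k)
    if eigval.min() < -1e-8 * max(eigval.max(), 1.0):
        raise ValueError("relationship matrix is not positive semi-definite")
    groups = sorted(t["group"].unique())
    if len(accessions) < len(groups) + 2:
        raise ValueError("fewer accessions than groups + 2")

    acc_idx = {a: i for i, a in enumerate(accessions)}
    z_rows = np.array([acc_idx[a] for a in t["accession"]])
    n = len(t)
    y = t["value"].to_numpy(float)
    cols = [np.ones(n)]
    for grp in groups[1:]:
        cols.append((t["group"] == grp).to_numpy(float))
    for b in sorted(t["batch"].unique())[1:]:
        cols.append((t["batch"] == b).to_numpy(float))
    x = np.column_stack(cols)
    p = np.linalg.matrix_rank(x)

    m = k[np.ix_(z_rows, z_rows)]  # Z K Z'
    lam, u = np.linalg.eigh(m)
    lam = np.clip(lam, 0.0, None)
    yt = u.T @ y
    xt = u.T @ x

    def neg2reml(h: float) -> float:
        w = h * lam + (1.0 - h)
        wi = 1.0 / w
        xtw = xt * wi[:, None]
        xwx = xt.T @ xtw
        sign, logdet_xwx = np.linalg.slogdet(xwx)
        beta = np.linalg.solve(xwx, xtw.T @ yt)
        resid = yt - xt @ beta
        rss = float(np.sum(resid**2 * wi))
        sigma2 = rss / (n - p)
        return (n - p) * np.log(sigma2) + float(np.sum(np.log(w))) + logdet_xwx

    res = optimize.minimize_scalar(
        neg2reml, bounds=(1e-6, 1.0 - 1e-6), method="bounded",
        options={"xatol": 1e-8},
    )
    h = float(res.x)
    w = h * lam + (1.0 - h)
    wi = 1.0 / w
    xtw = xt * wi[:, None]
    beta = np.linalg.solve(xt.T @ xtw, xtw.T @ yt)
    resid = yt - xt @ beta
    sigma2 = float(np.sum(resid**2 * wi)) / (n - p)
    return h * sigma2, (1.0 - h) * sigma2


# ----------------------------------------------------------------------
def qst(
    vc: VarianceComponents | None = None,
    f: float = 0.0,
    equation: int = 1,
    v_b: float | None = None,
    v_fam: float | None = None,
    v_aw: float | None = None,
) -> float:
    """QST from variance components (equation 1 or 2; see module docstring).

    Components can come from a :class:`VarianceComponents` or be passed
    directly.  Returns NaN when the ratio is 0/0.
    """
    if vc is not None:
        v_b = vc.v_b if v_b is None else v_b
        v_fam = vc.v_fam if v_fam is None else v_fam
        v_aw = vc.v_aw if v_aw is None else v_aw
    if v_b is None or v_b < 0:
        raise ValueError("v_b missing or negative")
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"inbreeding f outside [0,1]: {f}")
    if equation == 1:
        if v_fam is None or v_fam < 0:
            raise ValueError("equation 1 requires v_fam >= 0")
        den = v_b + v_fam
        return v_b / den if den > 0 else float("nan")
    if equation == 2:
        if v_aw is None or v_aw < 0:
            raise ValueError("equation 2 requires v_aw >= 0")
        den = (1 + f) * v_b + 2 * v_aw
        return (1 + f) * v_b / den if den > 0 else float("nan")
    raise ValueError("equation must be 1 or 2")


@dataclass
class QstResult:
    trait: str
    treatment: str
    qst: float
    equation: int
    f: float
    fst_mean: float
    fst_q95: float
    fst_q99: float
    exceeds_mean: bool
    exceeds_q95: bool
    exceeds_q99: bool


def qst_fst_compare(
    qst_values: dict[tuple[str, str], float],
    fst_per_site: np.ndarray,
    equation: int = 2,
    f: float = 0.0,
) -> list[QstResult]:
    """Flag trait QST values against the per-SNP FST distribution tails.

    Thresholds are the mean, 95th and 99th percentiles of the finite
    per-site FST values (the FST distribution should come from the same
    accessions that were phenotyped).
    """
    vals = np.asarray(fst_per_site, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("empty FST distribution")
    mean = float(vals.mean())
    q95 = float(np.percentile(vals, 95))
    q99 = float(np.percentile(vals, 99))
    out = []
    for (trait, treatment), q in sorted(qst_values.items()):
        out.append(
            QstResult(
                trait=trait, treatment=treatment, qst=float(q),
                equation=equation, f=f,
                fst_mean=mean, fst_q95=q95, fst_q99=q99,
                exceeds_mean=bool(q > mean),
                exceeds_q95=bool(q > q95),
                exceeds_q99=bool(q > q99),
            )
        )
    return out
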