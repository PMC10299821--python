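"""Genotype matrices, VCF I/O, site filtering, LD pruning and group assignment.

The central container is :class:`GenotypeMatrix`: a sites x samples matrix of
diploid alt-allele dosages (0/1/2, -1 for missing) with chromosome/position
metadata.  Invariant sites (no ALT allele) are first-class citizens because
the windowed diversity statistics require them for an unbiased denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

try:  # cyvcf2 is the standard reader; import lazily guarded for docs builds
    from cyvcf2 import VCF as _CyVCF
except ImportError:  # pragma: no cover
    _CyVCF = None

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "AncestryMatrix",
    "read_vcf",
    "write_vcf",
    "filter_sites",
    "ld_prune",
    "assign_groups",
    "genotype_r2_matrix",
]


@dataclass
class GenotypeMatrix:
    """Samples x sites diploid calls with site metadata.

    Attributes
    ----------
    samples : list of sample identifiers.
    chrom, pos : per-site chromosome label and 1-based position
        (positions strictly increasing within a chromosome).
    ref, alt : per-site reference allele and list of alternate alleles
        (empty list for invariant sites).
    calls : int8 array of shape (n_sites, n_samples); number of copies of
        the first alternate allele, ``MISSING`` (-1) for no-calls.
    multiallelic : per-site flag, True when >1 ALT allele was present.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: list[str]
    alt: list[list[str]]
    calls: np.ndarray
    multiallelic: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.multiallelic is None:
            self.multiallelic = np.array([len(a) > 1 for a in self.alt])
        self.multiallelic = np.asarray(self.multiallelic, dtype=bool)
        n_sites = len(self.pos)
        if self.calls.shape != (n_sites, len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n_sites} sites x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2, missing}")
        for ch in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == ch]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {ch}")

    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def is_variant(self) -> np.ndarray:
        """Sites with at least one ALT allele in the site record."""
        return np.array([len(a) > 0 for a in self.alt])

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=[self.ref[i] for i in idx],
            alt=[self.alt[i] for i in idx],
            calls=self.calls[idx],
            multiallelic=self.multiallelic[idx],
        )

    def take_samples(self, idx_or_names) -> "GenotypeMatrix":
        if len(idx_or_names) and isinstance(idx_or_names[0], str):
            lookup = {s: i for i, s in enumerate(self.samples)}
            idx = np.array([lookup[s] for s in idx_or_names])
        else:
            idx = np.asarray(idx_or_names)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            chrom=self.chrom,
            pos=self.pos,
            ref=list(self.ref),
            alt=list(self.alt),
            calls=self.calls[:, idx],
            multiallelic=self.multiallelic,
        )

    def variant_only(self) -> "GenotypeMatrix":
        return self.take_sites(np.flatnonzero(self.is_variant))

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=1)

    def allele_counts(self, sample_idx=None) -> tuple[np.ndarray, np.ndarray]:
        """(alt allele count, total called allele count) per site."""
        calls = self.calls if sample_idx is None else self.calls[:, sample_idx]
        obs = calls != MISSING
        alt = np.where(obs, calls, 0).sum(axis=1)
        return alt.astype(np.int64), 2 * obs.sum(axis=1).astype(np.int64)

    def dosages_imputed(self, sample_idx=None) -> np.ndarray:
        """Float dosage matrix with missing calls replaced by the site mean."""
        calls = self.calls if sample_idx is None else self.calls[:, sample_idx]
        d = calls.astype(float)
        miss = calls == MISSING
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(np.where(miss, np.nan, d), axis=1)
        means = np.nan_to_num(means, nan=0.0)
        return np.where(miss, means[:, None], d)


# ----------------------------------------------------------------------
# VCF I/O
def read_vcf(path: str, include_invariant: bool = True) -> GenotypeMatrix:
    """Read a VCF 4.2 file into a :class:`GenotypeMatrix`.

    Calls are mapped to first-ALT dosages; any genotype carrying a second
    or later alternate allele is set to missing and the site is flagged
    multiallelic (``filter_sites`` removes such sites).  Invariant sites
    (ALT ``.``) are kept only when ``include_invariant`` is true.
    """
    if _CyVCF is None:  # pragma: no cover
        raise ImportError("cyvcf2 is required to read VCF files")
    vcf = _CyVCF(path, gts012=False)
    samples = list(vcf.samples)
    chrom, pos, ref, alt, rows, multi = [], [], [], [], [], []
    for var in vcf:
        alts = [a for a in (var.ALT or []) if a not in (".", "")]
        if not alts and not include_invariant:
            continue
        row = np.empty(len(samples), dtype=np.int8)
        for j, g in enumerate(var.genotypes):
            alleles = [a for a in g[:-1] if a is not None]
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                row[j] = MISSING
            elif any(a > 1 for a in alleles):
                row[j] = MISSING  # non-primary alt -> masked
            else:
                row[j] = alleles[0] + alleles[1]
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(alts)
        multi.append(len(alts) > 1)
        rows.append(row)
    vcf.close()
    calls = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(samples)), np.int8)
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=ref,
        alt=alt,
        calls=calls,
        multiallelic=np.array(multi, dtype=bool),
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a normalized VCF 4.2 (GT only, unphased, missing as ``./.``)."""
    contigs = list(dict.fromkeys(g.chrom))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mungpop\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for ch in contigs:
            end = int(g.pos[g.chrom == ch].max()) if (g.chrom == ch).any() else 1
            fh.write(f"##contig=<ID={ch},length={end + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.samples) + "\n")
        for i in range(g.n_sites):
            alt = ",".join(g.alt[i]) if g.alt[i] else "."
            gts = "\t".join(_GT_STR[int(c)] for c in g.calls[i])
            fh.write(
                f"{g.chrom[i]}\t{g.pos[i]}\t.\t{g.ref[i]}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ----------------------------------------------------------------------
def filter_sites(
    g: GenotypeMatrix,
    max_missing: float = 0.10,
    biallelic_only: bool = True,
    verbose: bool = False,
) -> GenotypeMatrix:
    """Drop sites with more than two alleles or missingness above the cap.

    A site with missing fraction exactly equal to ``max_missing`` is kept
    (only "more than" the cap is removed).  Site order is preserved and the
    operation is idempotent.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError(f"max_missing outside [0,1]: {max_missing}")
    miss = g.missing_fraction()
    # tiny epsilon so a fraction equal to the cap up to float error is kept
    keep_miss = miss <= max_missing + 1e-12
    keep_allele = ~g.multiallelic if biallelic_only else np.ones(g.n_sites, bool)
    keep = keep_miss & keep_allele
    if verbose:
        print(
            f"filter_sites: removed {int((~keep_allele).sum())} multiallelic, "
            f"{int((keep_allele & ~keep_miss).sum())} high-missingness; "
            f"kept {int(keep.sum())}/{g.n_sites}"
        )
    return g.take_sites(np.flatnonzero(keep))


def genotype_r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between rows of a dosage matrix."""
    d = dosages - dosages.mean(axis=1, keepdims=True)
    sd = d.std(axis=1)
    sd[sd == 0] = np.nan
    r = (d @ d.T) / (len(dosages[0]) * np.outer(sd, sd))
    return np.nan_to_num(r * r, nan=0.0)


def ld_prune(
    g: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_threshold: float = 0.5,
) -> np.ndarray:
    """Sliding-window LD pruning, PLINK-style.

    Within each window of ``window_snps`` consecutive SNPs (advancing by
    ``step_snps``) any pair with genotype r-squared above the threshold
    loses its later-positioned member.  r-squared is computed on
    mean-imputed dosages.  Returns indices (into ``g``) of retained sites.
    """
    if window_snps < step_snps:
        raise ValueError("window must be at least as large as step")
    keep = np.ones(g.n_sites, dtype=bool)
    dos = g.dosages_imputed()
    for ch in dict.fromkeys(g.chrom):
        idx = np.flatnonzero(g.chrom == ch)
        n = len(idx)
        if n < 2:
            continue
        start = 0
        while True:
            stop = min(start + window_snps, n)
            widx = idx[start:stop]
            active = [i for i in widx if keep[i]]
            if len(active) > 1:
                r2 = genotype_r2_matrix(dos[active])
                for a in range(len(active)):
                    if not keep[active[a]]:
                        continue
                    for b in range(a + 1, len(active)):
                        if keep[active[b]] and r2[a, b] > r2_threshold:
                            keep[active[b]] = False
            if stop >= n:
                break
            start += step_snps
    return np.flatnonzero(keep)


# ----------------------------------------------------------------------
@dataclass
class AncestryMatrix:
    """Samples x K ancestry coefficients (rows sum to 1)."""

    samples: list[str]
    q: np.ndarray
    group_names: list[str] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[0] != len(self.samples):
            raise ValueError("q must be (n_samples, K)")
        if np.any(self.q < -1e-9) or np.any(self.q > 1 + 1e-9):
            raise ValueError("ancestry coefficients outside [0,1]")
        if np.any(np.abs(self.q.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("ancestry rows must sum to 1")
        if self.group_names is None:
            self.group_names = [f"group{k + 1}" for k in range(self.q.shape[1])]

    @classmethod
    def from_table(cls, path: str, samples: list[str], group_names=None):
        q = np.loadtxt(path, ndmin=2)
        return cls(samples=samples, q=q, group_names=group_names)


def assign_groups(q: AncestryMatrix, threshold: float = 0.7) -> dict[str, str]:
    """Assign each sample to its majority group when Q >= threshold.

    Samples whose largest coefficient falls below the threshold are labelled
    ``"admixed"``.  The boundary is inclusive (Q equal to the threshold
    assigns).  A threshold of 0.5 reproduces the usual sensitivity analysis.
    """
    best = q.q.argmax(axis=1)
    out = {}
    for i, s in enumerate(q.samples):
        if q.q[i, best[i]] >= threshold - 1e-12:
            out[s] = q.group_names[best[i]]
        else:
            out[s] = "admixed"
    return out
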