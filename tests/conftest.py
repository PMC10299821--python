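import numpy as np
import pytest
from hypothesis import settings

from mungpop.genotypes import GenotypeMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_genotypes(calls, chrom=None, pos=None, samples=None, alt=None):
    """Build a GenotypeMatrix from a plain call matrix (sites x samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    if chrom is None:
        chrom = ["chr1"] * n_sites
    if pos is None:
        pos = []
        counters = {}
        for c in chrom:
            counters[c] = counters.get(c, 0) + 1
            pos.append(counters[c] * 100)
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if alt is None:
        alt = [["T"]] * n_sites
    return GenotypeMatrix(
        samples=samples,
        chrom=chrom,
        pos=pos,
        ref=["A"] * n_sites,
        alt=alt,
        calls=calls,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_pi(calls_pop):
    """Reference pi: enumerate every allele pair at every site.

    ``calls_pop``: sites x samples dosage matrix (-1 missing).  Each called
    diploid contributes two allele copies; all pairs of copies are compared.
    """
    num = den = 0
    for site in calls_pop:
        alleles = []
        for c in site:
            if c == -1:
                continue
            alleles += [1] * int(c) + [0] * (2 - int(c))
        for i in range(len(alleles)):
            for j in range(i + 1, len(alleles)):
                den += 1
                num += alleles[i] != alleles[j]
    return num, den


def brute_force_dxy(calls_a, calls_b):
    """Reference dxy: enumerate every between-population allele pair."""
    num = den = 0
    for sa, sb in zip(calls_a, calls_b):
        al_a, al_b = [], []
        for c in sa:
            if c != -1:
                al_a += [1] * int(c) + [0] * (2 - int(c))
        for c in sb:
            if c != -1:
                al_b += [1] * int(c) + [0] * (2 - int(c))
        for x in al_a:
            for y in al_b:
                den += 1
                num += x != y
    return num, den
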