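"""Population-genetics QC: allele frequencies, Hardy-Weinberg tests, LD,
and EM haplotype-frequency estimation from unphased genotypes.

Two HWE tests are provided. The exact conditional test enumerates every
heterozygote count compatible with the observed allele counts and sums the
probabilities of configurations no more probable than the observed one
(two-sided, Wigginton-style). The 1-df Pearson chi-square test compares the
observed genotype tallies with the p^2, 2pq, q^2 expectations. Candidate-SNP
panels are routinely reported with the exact test; both values appear in the
QC report.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .io_cohort import GenotypeMatrix


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype tallies at one biallelic SNP."""

    n_hom_major: int
    n_het: int
    n_hom_minor: int

    def __post_init__(self) -> None:
        if min(self.n_hom_major, self.n_het, self.n_hom_minor) < 0:
            raise ValueError("negative genotype count")
        if self.total == 0:
            raise ValueError("all-zero genotype counts")

    @property
    def total(self) -> int:
        return self.n_hom_major + self.n_het + self.n_hom_minor

    @classmethod
    def from_matrix(cls, gm: GenotypeMatrix, snp_id: str) -> "GenotypeCounts":
        return cls(*gm.genotype_counts(snp_id))


@dataclass(frozen=True)
class HweResult:
    p_exact: float
    chi2_stat: float
    p_chi2: float


@dataclass(frozen=True)
class LdResult:
    d: float
    d_prime: float
    r_squared: float
    defined: bool = True


@dataclass
class HaplotypeFreqs:
    """EM-estimated haplotype frequencies over a SNP subset.

    ``freqs`` maps allele-string haplotypes (one character per SNP, panel
    order) to frequencies summing to one. Haplotypes with frequency below
    ``rare_threshold`` are listed in ``rare``.
    """

    freqs: dict[str, float]
    log_likelihood: float
    n_iterations: int
    rare_threshold: float
    rare: list[str]


def allele_frequency(counts: GenotypeCounts) -> float:
    """Major-allele frequency (2*hom_major + het) / 2n."""
    return (2 * counts.n_hom_major + counts.n_het) / (2 * counts.total)


def _het_log_probs(n: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of every heterozygote count compatible with the
    conditional distribution given allele counts (n_rare minor alleles in n
    diploids)."""
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    return hets, logp


def hwe_exact(counts: GenotypeCounts) -> float:
    """Two-sided exact conditional HWE test.

    Conditions on the observed allele counts, enumerates all compatible
    heterozygote counts, and sums the probabilities of configurations with
    probability <= that of the observed configuration.
    """
    n = counts.total
    n_rare = min(
        2 * counts.n_hom_major + counts.n_het, 2 * counts.n_hom_minor + counts.n_het
    )
    hets, logp = _het_log_probs(n, n_rare)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, counts.n_het)]
    # relative tolerance guards against float noise when tying with p_obs
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_chi2(counts: GenotypeCounts) -> tuple[float, float]:
    """1-df Pearson chi-square against HWE expectations, no continuity
    correction. Monomorphic counts give (0, 1) by convention."""
    n = counts.total
    p = allele_frequency(counts)
    q = 1 - p
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([counts.n_hom_major, counts.n_het, counts.n_hom_minor])
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_test(counts: GenotypeCounts) -> HweResult:
    chi2, p_chi2 = hwe_chi2(counts)
    return HweResult(hwe_exact(counts), chi2, p_chi2)


# ---------------------------------------------------------------------------
# EM haplotype frequencies


def _compatible_pairs(geno: tuple[int, ...]) -> list[tuple[int, int]]:
    """Unordered haplotype pairs compatible with a genotype vector.

    Haplotypes are bitmasks (bit j set = minor allele at SNP j). A subject
    heterozygous at h loci is compatible with 2^(h-1) unordered pairs.
    """
    het = [j for j, g in enumerate(geno) if g == 1]
    base = sum(1 << j for j, g in enumerate(geno) if g == 2)
    if not het:
        return [(base, base)]
    pairs = []
    first = het[0]
    for bits in product((0, 1), repeat=len(het) - 1):
        h1 = base | (1 << first)
        h2 = base
        for j, b in zip(het[1:], bits):
            if b:
                h1 |= 1 << j
            else:
                h2 |= 1 << j
        pairs.append((h1, h2))
    return pairs


def em_haplotypes(
    gm: GenotypeMatrix,
    snp_subset: list[str],
    rare_threshold: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeFreqs:
    """Maximum-likelihood haplotype frequencies under HWE via EM.

    Subjects with a missing call at any subset SNP are excluded. Converges
    when the log-likelihood gain drops below ``tol`` (or at ``max_iter``).
    """
    if not snp_subset:
        raise ValueError("empty SNP subset")
    if len(snp_subset) > 6:
        raise ValueError("haplotype enumeration limited to 6 SNPs")
    idx = [gm.snp_index(s) for s in snp_subset]
    sub = gm.codes[:, idx]
    complete = sub[(sub >= 0).all(axis=1)]
    if complete.shape[0] == 0:
        raise ValueError("no complete genotype vectors for subset")
    k = len(idx)
    n_h = 1 << k

    genos, counts = np.unique(complete, axis=0, return_counts=True)
    pair_lists = [_compatible_pairs(tuple(g)) for g in genos]

    # start from the product of single-locus allele frequencies
    minor = complete.mean(axis=0) / 2.0
    f = np.ones(n_h)
    for h in range(n_h):
        for j in range(k):
            f[h] *= minor[j] if (h >> j) & 1 else 1 - minor[j]
    f = np.clip(f, 1e-12, None)
    f /= f.sum()

    n_chrom = 2.0 * counts.sum()
    ll_prev = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        expected = np.zeros(n_h)
        ll = 0.0
        for (pairs, c) in zip(pair_lists, counts):
            w = np.array(
                [(2.0 if h1 != h2 else 1.0) * f[h1] * f[h2] for h1, h2 in pairs]
            )
            tot = w.sum()
            ll += c * np.log(tot)
            w *= c / tot
            for (h1, h2), wi in zip(pairs, w):
                expected[h1] += wi
                expected[h2] += wi
        f = expected / n_chrom
        if ll - ll_prev < tol and n_iter > 1:
            ll_prev = ll
            break
        ll_prev = ll

    labels = {}
    for h in range(n_h):
        chars = [
            gm.panel[idx[j]].allele_minor if (h >> j) & 1 else gm.panel[idx[j]].allele_major
            for j in range(k)
        ]
        labels[h] = "".join(chars)
    freqs = {labels[h]: float(f[h]) for h in range(n_h)}
    rare = [hap for hap, fr in freqs.items() if fr < rare_threshold]
    return HaplotypeFreqs(freqs, float(ll_prev), n_iter, rare_threshold, rare)


def haplotype_dosages(
    gm: GenotypeMatrix, snp_subset: list[str], hf: HaplotypeFreqs
) -> "np.ndarray":
    """Posterior-mean haplotype dosage per subject (n_subjects x n_haplotypes).

    Subjects with missing calls in the subset get NaN rows. Column order
    follows ``sorted(hf.freqs)``.
    """
    idx = [gm.snp_index(s) for s in snp_subset]
    sub = gm.codes[:, idx]
    k = len(idx)
    labels = sorted(hf.freqs)
    hap_col = {}
    for h in range(1 << k):
        chars = "".join(
            gm.panel[idx[j]].allele_minor if (h >> j) & 1 else gm.panel[idx[j]].allele_major
            for j in range(k)
        )
        hap_col[h] = labels.index(chars)
    f = np.zeros(1 << k)
    for h, col in hap_col.items():
        f[h] = hf.freqs[labels[col]]

    out = np.full((gm.n_subjects, len(labels)), np.nan)
    for i in range(gm.n_subjects):
        g = sub[i]
        if (g < 0).any():
            continue
        pairs = _compatible_pairs(tuple(g))
        w = np.array([(2.0 if a != b else 1.0) * f[a] * f[b] for a, b in pairs])
        if w.sum() == 0:
            w = np.ones_like(w)
        w /= w.sum()
        row = np.zeros(len(labels))
        for (a, b), wi in zip(pairs, w):
            row[hap_col[a]] += wi
            row[hap_col[b]] += wi
        out[i] = row
    return out


def ld_pair(gm: GenotypeMatrix, snp_a: str, snp_b: str) -> LdResult:
    """Pairwise LD (D', r^2) from EM two-locus haplotype frequencies.

    D is computed for the major-allele haplotype; a monomorphic locus gives
    an undefined (flagged) result.
    """
    ca = GenotypeCounts.from_matrix(gm, snp_a)
    cb = GenotypeCounts.from_matrix(gm, snp_b)
    p_a = allele_frequency(ca)
    p_b = allele_frequency(cb)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LdResult(np.nan, np.nan, np.nan, defined=False)
    hf = em_haplotypes(gm, [snp_a, snp_b])
    maj = gm.panel[gm.snp_index(snp_a)].allele_major + gm.panel[
        gm.snp_index(snp_b)
    ].allele_major
    p_ab = hf.freqs[maj]
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LdResult(float(d), float(min(d_prime, 1.0)), float(min(r2, 1.0)))
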