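"""Variant-level statistics for rare-variant cohort analyses.

Allele/genotype frequency arithmetic, the Hardy-Weinberg exact test, pairwise
IBD estimation by the method of moments, EM-based two-locus linkage
disequilibrium, haplotype-span arithmetic, Fisher's-method meta-analysis,
power/sample-size calculation for a variant of known variance explained, and
a frequency-based neutral allele-age estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, isinf

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .containers import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class VariantCounts:
    """Genotype counts for one biallelic variant (alt = counted allele)."""

    n_ref_hom: int
    n_het: int
    n_alt_hom: int

    def __post_init__(self) -> None:
        if min(self.n_ref_hom, self.n_het, self.n_alt_hom) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_ref_hom + self.n_het + self.n_alt_hom

    @property
    def n_alt_alleles(self) -> int:
        return 2 * self.n_alt_hom + self.n_het


@dataclass(frozen=True)
class LDResult:
    """Normalised two-locus linkage disequilibrium."""

    d: float
    d_prime: float
    r2: float
    hap_freqs: tuple[float, float, float, float]  # (AB, Ab, aB, ab)


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------


def allele_frequency(counts) -> float:
    """Alt-allele frequency from genotype counts or an ``(n_alt, n_ref)``
    allele-count pair."""
    if isinstance(counts, VariantCounts):
        if counts.total == 0:
            raise ValueError("no genotypes")
        return counts.n_alt_alleles / (2.0 * counts.total)
    n_alt, n_ref = counts
    if n_alt < 0 or n_ref < 0 or n_alt + n_ref == 0:
        raise ValueError("allele counts must be non-negative and sum > 0")
    return n_alt / (n_alt + n_ref)


def het_fraction(counts: VariantCounts) -> float:
    """Fraction of individuals heterozygous at the variant."""
    if counts.total == 0:
        raise ValueError("no genotypes")
    return counts.n_het / counts.total


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(counts: VariantCounts) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote configuration no more probable than the observed one.
    Monomorphic variants return p = 1 by convention.
    """
    n = counts.total
    if n == 0:
        raise ValueError("no genotypes")
    n_minor = min(counts.n_alt_alleles, 2 * n - counts.n_alt_alleles)
    if n_minor == 0:
        return 1.0
    # possible het counts share the parity of the minor-allele count
    het = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - het) // 2
    hom_major = n - het - hom_minor
    # log P(het | n, n_minor) up to a constant:
    #   n! / (hom_major! het! hom_minor!) * 2^het
    logw = (
        het * np.log(2.0)
        - gammaln(hom_major + 1)
        - gammaln(het + 1)
        - gammaln(hom_minor + 1)
    )
    logw -= logsumexp(logw)
    obs = np.searchsorted(het, counts.n_het)
    if obs >= len(het) or het[obs] != counts.n_het:
        raise ValueError("observed het count inconsistent with allele counts")
    # tolerance guards float ties between configurations of equal probability
    keep = logw <= logw[obs] + 1e-12
    return float(min(1.0, np.exp(logsumexp(logw[keep]))))


# ---------------------------------------------------------------------------
# pairwise IBD (method of moments on IBS counts)
# ---------------------------------------------------------------------------


def pairwise_ibd(g: GenotypeMatrix, pairs=None) -> pd.DataFrame:
    """Method-of-moments genome-wide IBD for sample pairs.

    Follows the classic IBS-based estimator: per-pair counts of loci sharing
    0/1/2 alleles identical by state are compared with their expectations
    under IBD state 0/1/2 given the sample allele frequencies, giving
    P(IBD=k) and the summary pi-hat = P(IBD=1)/2 + P(IBD=2), clamped to
    [0, 1].  No small-sample frequency correction is applied.

    Returns a data frame with columns ``sample_i, sample_j, ibd0, ibd1, ibd2,
    pi_hat``.
    """
    freq = g.alt_allele_frequency()
    poly = (freq > 0) & (freq < 1) & ~np.isnan(freq)
    if poly.sum() == 0:
        raise ValueError("no polymorphic variants for IBD estimation")
    geno = g.genotypes[:, poly].astype(np.int16)
    p = freq[poly]
    q = 1.0 - p

    # expected per-locus IBS probabilities by IBD state, summed over loci
    e_ibs0_z0 = 2 * p**2 * q**2
    e_ibs1_z0 = 4 * p**3 * q + 4 * p * q**3
    e_ibs2_z0 = p**4 + q**4 + 4 * p**2 * q**2
    e_ibs1_z1 = 2 * p**2 * q + 2 * p * q**2
    e_ibs2_z1 = p**3 + q**3 + p**2 * q + p * q**2

    if pairs is None:
        n = g.n_samples
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        pairs = [
            (
                a if isinstance(a, int) else g.sample_index(a),
                b if isinstance(b, int) else g.sample_index(b),
            )
            for a, b in pairs
        ]

    rows = []
    for i, j in pairs:
        gi, gj = geno[i], geno[j]
        ok = (gi != MISSING) & (gj != MISSING)
        diff = np.abs(gi[ok] - gj[ok])
        ibs0 = float((diff == 2).sum())
        ibs1 = float((diff == 1).sum())
        ibs2 = float((diff == 0).sum())
        E0_0 = e_ibs0_z0[ok].sum()
        z0 = ibs0 / E0_0 if E0_0 > 0 else 0.0
        E1_1 = e_ibs1_z1[ok].sum()
        z1 = (ibs1 - z0 * e_ibs1_z0[ok].sum()) / E1_1 if E1_1 > 0 else 0.0
        n_ok = float(ok.sum())
        z2 = (ibs2 - z0 * e_ibs2_z0[ok].sum() - z1 * e_ibs2_z1[ok].sum()) / n_ok
        z = np.clip([z0, z1, z2], 0.0, 1.0)
        total = z.sum()
        if total > 0:
            z = z / total
        pi_hat = float(np.clip(z[1] / 2.0 + z[2], 0.0, 1.0))
        rows.append((g.samples[i], g.samples[j], z[0], z[1], z[2], pi_hat))
    return pd.DataFrame(
        rows, columns=["sample_i", "sample_j", "ibd0", "ibd1", "ibd2", "pi_hat"]
    )


def fraction_low_ibd(ibd: pd.DataFrame, threshold: float = 0.10) -> float:
    """Fraction of pairs with pi-hat at or below ``threshold``."""
    if len(ibd) == 0:
        raise ValueError("no pairs")
    return float((ibd["pi_hat"] <= threshold).mean())


# ---------------------------------------------------------------------------
# EM linkage disequilibrium
# ---------------------------------------------------------------------------


def ld_em(
    g: GenotypeMatrix,
    variant_a: int,
    variant_b: int,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LDResult:
    """D', r-squared and haplotype frequencies for two variants by EM.

    Two-locus haplotype frequencies are estimated by expectation-maximisation
    over the double-heterozygote phase ambiguity, initialised at linkage
    equilibrium.  The log-likelihood is checked to be non-decreasing at every
    iteration.
    """
    ga = g.genotypes[:, variant_a].astype(int)
    gb = g.genotypes[:, variant_b].astype(int)
    ok = (ga != MISSING) & (gb != MISSING)
    ga, gb = ga[ok], gb[ok]
    n = len(ga)
    if n == 0:
        raise ValueError("no complete genotype pairs")
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((ga == i) & (gb == j))
    return ld_em_from_counts(counts, tol=tol, max_iter=max_iter)


def ld_em_from_counts(
    counts: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> LDResult:
    """EM haplotype-frequency LD from a 3x3 joint genotype count table.

    ``counts[i, j]`` is the number of individuals with i copies of allele A
    (locus 1) and j copies of allele B (locus 2).  Alleles: A/a, B/b; the
    four haplotypes are AB, Ab, aB, ab.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty count table")
    pA = (2 * counts[2, :].sum() + counts[1, :].sum()) / (2 * n)
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("LD undefined for monomorphic variants")

    # haplotype counts fixed by genotype except for double heterozygotes
    n_dh = counts[1, 1]
    base = np.zeros(4)  # AB, Ab, aB, ab
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            c = counts[i, j]
            # each individual contributes two haplotypes with known phase
            a_alleles = [1] * i + [0] * (2 - i)
            b_alleles = [1] * j + [0] * (2 - j)
            for ha, hb in zip(a_alleles, b_alleles):
                base[(1 - ha) * 2 + (1 - hb)] += c
    # base indices: 0=AB, 1=Ab, 2=aB, 3=ab

    h = np.array(
        [pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)]
    )  # linkage-equilibrium start

    def loglik(h4: np.ndarray) -> float:
        ll = 0.0
        with np.errstate(divide="ignore"):
            lh = np.log(np.maximum(h4, 1e-300))
        ll += base @ lh
        if n_dh > 0:
            ll += n_dh * np.log(max(2 * h4[0] * h4[3] + 2 * h4[1] * h4[2], 1e-300))
        return ll

    prev_ll = loglik(h)
    for _ in range(max_iter):
        denom = h[0] * h[3] + h[1] * h[2]
        if n_dh > 0 and denom > 0:
            w_cis = h[0] * h[3] / denom  # P(AB/ab | double het)
        else:
            w_cis = 0.5
        new = base.copy()
        new[0] += n_dh * w_cis
        new[3] += n_dh * w_cis
        new[1] += n_dh * (1 - w_cis)
        new[2] += n_dh * (1 - w_cis)
        new = new / (2 * n)
        ll = loglik(new)
        if ll < prev_ll - 1e-8:
            raise AssertionError("EM log-likelihood decreased")
        delta = np.abs(new - h).max()
        h = new
        prev_ll = ll
        if delta < tol:
            break

    D = h[0] - pA * pB
    if D >= 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = abs(D) / d_max if d_max > 0 else 0.0
    r2 = D**2 / (pA * (1 - pA) * pB * (1 - pB))
    return LDResult(
        d=float(D),
        d_prime=float(min(1.0, d_prime)),
        r2=float(min(1.0, r2)),
        hap_freqs=tuple(float(x) for x in h),
    )


# ---------------------------------------------------------------------------
# haplotype span arithmetic
# ---------------------------------------------------------------------------


def haplotype_span(start_bp: int, end_bp: int) -> tuple[int, int]:
    """Span between two physical coordinates as ``(bp, kb)``; kb is floored."""
    if end_bp < start_bp:
        raise ValueError("end must be >= start")
    bp = int(end_bp) - int(start_bp)
    return bp, bp // 1000


def shared_carrier_haplotype(
    haplotypes: np.ndarray, positions: np.ndarray, focal_pos: int
):
    """Maximal interval over which all carrier haplotypes are identical.

    ``haplotypes`` is a ``(k, m)`` 0/1 allele matrix of phased carrier
    haplotypes; every haplotype must carry the derived (1) allele at the focal
    site.  Returns ``(start_bp, end_bp)`` (closed, at the outermost identical
    variant) plus a list of per-pair extended intervals.
    """
    haplotypes = np.asarray(haplotypes)
    positions = np.asarray(positions)
    if haplotypes.ndim != 2 or haplotypes.shape[0] < 2:
        raise ValueError("need at least two phased carrier haplotypes")
    fi = int(np.searchsorted(positions, focal_pos))
    if fi >= len(positions) or positions[fi] != focal_pos:
        raise ValueError("focal position not among variant positions")
    if np.any(haplotypes[:, fi] != 1):
        raise ValueError("every carrier haplotype must carry the focal allele")

    def _interval(haps: np.ndarray) -> tuple[int, int]:
        same = np.all(haps == haps[0], axis=0)
        left = fi
        while left > 0 and same[left - 1]:
            left -= 1
        right = fi
        while right < len(positions) - 1 and same[right + 1]:
            right += 1
        return int(positions[left]), int(positions[right])

    overall = _interval(haplotypes)
    pair_intervals = {}
    k = haplotypes.shape[0]
    for a in range(k):
        for b in range(a + 1, k):
            pair_intervals[(a, b)] = _interval(haplotypes[[a, b]])
    return overall, pair_intervals


# ---------------------------------------------------------------------------
# meta-analysis, power, allele age
# ---------------------------------------------------------------------------


def fisher_meta(p_values) -> tuple[float, float]:
    """Fisher's method: combine independent p-values.

    Returns ``(X2, combined_p)`` with X2 = -2 * sum(ln p) referred to a
    chi-square with 2k degrees of freedom.
    """
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = float(-2.0 * np.log(p).sum())
    return x2, float(stats.chi2.sf(x2, 2 * len(p)))


def variance_explained_biallelic(maf: float, beta_std: float) -> float:
    """Trait variance fraction from an additive biallelic variant:
    2 f (1-f) beta_std^2 on a unit-variance trait."""
    return 2.0 * maf * (1.0 - maf) * beta_std**2


def required_sample_size(
    variance_explained: float | None = None,
    maf: float | None = None,
    beta_std: float | None = None,
    alpha: float = 5e-8,
    power: float = 0.8,
) -> float:
    """Sample size needed to detect an additive variant at the given power.

    Normal approximation: the per-individual non-centrality equals the
    variance explained, so N = (z_{1-alpha/2} + z_{power})^2 / VE, rounded up.
    Supply either ``variance_explained`` directly or ``maf`` + ``beta_std``.
    """
    if variance_explained is None:
        if maf is None or beta_std is None:
            raise ValueError("need variance_explained or (maf, beta_std)")
        variance_explained = variance_explained_biallelic(maf, beta_std)
    if not 0 <= variance_explained < 1:
        raise ValueError("variance explained must lie in [0, 1)")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if variance_explained == 0:
        return float("inf")
    z = stats.norm.isf(alpha / 2) + stats.norm.ppf(power)
    return float(ceil(z**2 / variance_explained))


def allele_age_frequency(
    freq: float, effective_size: float = 10_000, generation_years: float = 25.0
) -> dict[str, float]:
    """Neutral frequency-based allele age (Kimura-Ohta expectation).

    Expected age of a neutral allele at frequency p in a population of
    effective size Ne: t = -4 Ne p ln(p) / (1 - p) generations.
    Returns the age in generations and in years.
    """
    if not 0 < freq < 1:
        raise ValueError("frequency must lie in (0, 1)")
    if effective_size <= 0:
        raise ValueError("effective size must be positive")
    gens = -4.0 * effective_size * freq * np.log(freq) / (1.0 - freq)
    return {"generations": float(gens), "years": float(gens * generation_years)}
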