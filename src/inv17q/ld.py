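"""Two-locus linkage disequilibrium from unphased genotypes.

Haplotype frequencies for a pair of biallelic loci are estimated from the
3x3 table of two-locus genotype classes by EM under random union of gametes;
only the double-heterozygote cell is ambiguous (cis AB/ab versus trans Ab/aB)
and is split by its posterior phase probability each iteration.  From the
fitted frequencies the usual pairwise statistics follow: D, Lewontin's D',
the squared allelic correlation r2, and the base-10 LOD score of the fitted
haplotype frequencies against linkage equilibrium at the observed allele
margins.  A chi-square Hardy-Weinberg check and the +/-50 kb surrogate-SNP
selection rule (rank by LOD, ties by distance) complete the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from inv17q.genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

LN10 = np.log(10.0)


class MonomorphicLocusError(ValueError):
    """LD statistics are undefined when a locus carries a single allele."""


@dataclass
class TwoLocusCounts:
    """3x3 subject counts by genotype class; index = copies of the second
    (lowercase) allele at each locus: 0 = hom-A, 1 = het, 2 = hom-a."""

    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (3, 3):
            raise ValueError("two-locus table must be 3x3")
        if (self.table < 0).any():
            raise ValueError("negative counts")
        if self.table.sum() <= 0:
            raise ValueError("empty table")

    @property
    def n(self) -> float:
        return float(self.table.sum())


@dataclass
class LdResult:
    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    D: float = np.nan
    D_prime: float = np.nan
    r2: float = np.nan
    lod: float = np.nan
    em_iters: int = 0
    converged: bool = False

    @property
    def freqs(self) -> np.ndarray:
        return np.array([self.p_AB, self.p_Ab, self.p_aB, self.p_ab])


def genotype_class_probs(freqs: np.ndarray) -> np.ndarray:
    """3x3 genotype-class probabilities under random union of gametes.

    ``freqs`` = (p_AB, p_Ab, p_aB, p_ab); haplotype h carries (i_h, j_h)
    copies of the lowercase alleles.
    """
    dosage = [(0, 0), (0, 1), (1, 0), (1, 1)]  # (a-count, b-count) per haplotype
    probs = np.zeros((3, 3))
    for h1 in range(4):
        for h2 in range(4):
            i = dosage[h1][0] + dosage[h2][0]
            j = dosage[h1][1] + dosage[h2][1]
            probs[i, j] += freqs[h1] * freqs[h2]
    return probs


def _loglik(freqs: np.ndarray, table: np.ndarray) -> float:
    probs = genotype_class_probs(freqs)
    mask = table > 0
    with np.errstate(divide="ignore"):
        lp = np.log(probs[mask])
    if np.any(np.isneginf(lp)):
        return -np.inf
    return float(np.sum(table[mask] * lp))


def em_haplotypes(
    counts: TwoLocusCounts, tol: float = 1e-8, max_iter: int = 1000
) -> LdResult:
    """EM estimate of the four haplotype frequencies from a 3x3 genotype table.

    Initialized at linkage equilibrium (products of observed allele
    frequencies); stops when the largest frequency change is below ``tol``.
    Degenerate tables leave frequencies at the boundary — no pseudocounts.
    """
    t = counts.table
    n = counts.n
    # observed allele frequencies (a = lowercase at locus 1, b at locus 2)
    p_a = (t[1, :].sum() + 2 * t[2, :].sum()) / (2 * n)
    p_b = (t[:, 1].sum() + 2 * t[:, 2].sum()) / (2 * n)
    p_A, p_B = 1 - p_a, 1 - p_b
    freqs = np.array([p_A * p_B, p_A * p_b, p_a * p_B, p_a * p_b])

    converged = False
    it = 0
    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        p_AB, p_Ab, p_aB, p_ab = freqs
        cis = p_AB * p_ab
        trans = p_Ab * p_aB
        c = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        n_AB = 2 * t[0, 0] + t[0, 1] + t[1, 0] + c * t[1, 1]
        n_Ab = 2 * t[0, 2] + t[0, 1] + t[1, 2] + (1 - c) * t[1, 1]
        n_aB = 2 * t[2, 0] + t[1, 0] + t[2, 1] + (1 - c) * t[1, 1]
        n_ab = 2 * t[2, 2] + t[1, 2] + t[2, 1] + c * t[1, 1]
        new = np.array([n_AB, n_Ab, n_aB, n_ab]) / (2 * n)
        ll = _loglik(new, t)
        if ll < prev_ll - 1e-9:  # EM guarantee; violation signals a bug
            raise AssertionError("EM log-likelihood decreased")
        delta = float(np.max(np.abs(new - freqs)))
        freqs = new
        prev_ll = ll
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("em_haplotypes: no convergence after %d iterations", max_iter)
    return LdResult(
        p_AB=freqs[0], p_Ab=freqs[1], p_aB=freqs[2], p_ab=freqs[3],
        em_iters=it, converged=converged,
    )


def ld_stats(freqs: LdResult | np.ndarray, counts: TwoLocusCounts) -> LdResult:
    """D, D', r2 and LOD from haplotype frequencies and the observed table.

    D' scales D by its admissible bound given the allele frequencies; the LOD
    is log10 of the multinomial likelihood ratio of the fitted frequencies
    against independence at the same allele margins.
    """
    if isinstance(freqs, LdResult):
        res = freqs
        f = res.freqs
    else:
        f = np.asarray(freqs, dtype=float)
        res = LdResult(p_AB=f[0], p_Ab=f[1], p_aB=f[2], p_ab=f[3], converged=True)
    p_A = f[0] + f[1]
    p_a = f[2] + f[3]
    p_B = f[0] + f[2]
    p_b = f[1] + f[3]
    for name, freq in (("locus1", min(p_A, p_a)), ("locus2", min(p_B, p_b))):
        if freq <= 0:
            raise MonomorphicLocusError(f"{name} is monomorphic; D' and r2 undefined")
    D = f[0] - p_A * p_B
    if D > 0:
        d_max = min(p_A * p_b, p_a * p_B)
    else:
        d_max = min(p_A * p_B, p_a * p_b)
    D_prime = D / d_max if d_max > 0 else 0.0
    r2 = D * D / (p_A * p_a * p_B * p_b)
    indep = np.array([p_A * p_B, p_A * p_b, p_a * p_B, p_a * p_b])
    lod = (_loglik(f, counts.table) - _loglik(indep, counts.table)) / LN10
    lod = max(lod, 0.0)  # clip tiny negative rounding at D ~ 0
    res.D = float(D)
    res.D_prime = float(D_prime)
    res.r2 = float(r2)
    res.lod = float(lod)
    return res


def pair_ld(counts: TwoLocusCounts, tol: float = 1e-8, max_iter: int = 1000) -> LdResult:
    """EM haplotype frequencies followed by the LD statistics."""
    return ld_stats(em_haplotypes(counts, tol=tol, max_iter=max_iter), counts)


def hwe_chi2(n_AA: float, n_Aa: float, n_aa: float) -> tuple[float, float]:
    """1-df chi-square Hardy-Weinberg test; returns (chi2, p).

    Monomorphic samples return (0, 1): no departure is testable.
    """
    n = n_AA + n_Aa + n_aa
    if n <= 0:
        raise ValueError("no subjects")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    if p <= 0 or q <= 0:
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def two_locus_counts(gm: GenotypeMatrix, j1: int, j2: int) -> TwoLocusCounts:
    """Cross-tabulate two SNP columns into a 3x3 genotype-class table,
    dropping subjects missing at either locus."""
    snp1, snp2 = gm.snps[j1], gm.snps[j2]
    for snp in (snp1, snp2):
        if snp.allele_a is None:
            raise MonomorphicLocusError(f"{snp.snp_id} has no observed alleles")
    a1 = snp1.allele_b if snp1.allele_b is not None else "?"
    a2 = snp2.allele_b if snp2.allele_b is not None else "?"
    d1 = gm.genotype_dosage(j1, a1)
    d2 = gm.genotype_dosage(j2, a2)
    ok = (d1 >= 0) & (d2 >= 0)
    table = np.zeros((3, 3))
    for i, j in zip(d1[ok], d2[ok]):
        table[i, j] += 1
    return TwoLocusCounts(table=table)


@dataclass
class SurrogateChoice:
    target_snp: str
    chosen: list[str]
    candidates: pd.DataFrame  # snp_id, distance_bp, d_prime, r2, lod, hwe_p, qualifies


def select_surrogates(
    gm: GenotypeMatrix,
    target_snp_id: str,
    window: int = 50_000,
    lod_min: float = 3.0,
    hwe_alpha: float = 0.05,
    n_choose: int = 2,
) -> SurrogateChoice:
    """Choose up to ``n_choose`` surrogate SNPs for a target within +/-window bp.

    Candidates on the target's chromosome within the closed window are kept if
    their genotype frequencies are consistent with Hardy-Weinberg equilibrium
    (chi-square p >= ``hwe_alpha``) and their LOD versus the target reaches
    ``lod_min``; ranking is by LOD descending with ties broken by absolute
    distance (both chosen SNPs may sit on the same side of the target).
    Distance is signed: negative = upstream (lower coordinate) of the target.
    """
    jt = gm.snp_index(target_snp_id)
    target = gm.snps[jt]
    rows = []
    for j, snp in enumerate(gm.snps):
        if j == jt or str(snp.chrom) != str(target.chrom):
            continue
        dist = snp.pos - target.pos
        if abs(dist) > window:
            continue
        try:
            counts = two_locus_counts(gm, jt, j)
            res = pair_ld(counts)
        except MonomorphicLocusError:
            continue
        geno = counts.table.sum(axis=0)  # margins of the candidate locus
        _, hwe_p = hwe_chi2(geno[0], geno[1], geno[2])
        rows.append(
            {
                "snp_id": snp.snp_id,
                "distance_bp": dist,
                "d_prime": res.D_prime,
                "r2": res.r2,
                "lod": res.lod,
                "hwe_p": hwe_p,
                "qualifies": bool(hwe_p >= hwe_alpha and res.lod >= lod_min),
            }
        )
    df = pd.DataFrame(
        rows, columns=["snp_id", "distance_bp", "d_prime", "r2", "lod", "hwe_p", "qualifies"]
    )
    if len(df):
        df["abs_dist"] = df["distance_bp"].abs()
        df = df.sort_values(["qualifies", "lod", "abs_dist"], ascending=[False, False, True])
        df = df.drop(columns="abs_dist").reset_index(drop=True)
    chosen = df.loc[df["qualifies"], "snp_id"].head(n_choose).tolist() if len(df) else []
    if not chosen:
        logger.warning(
            "select_surrogates: no qualifying candidate for %s "
            "(window=%d, lod_min=%.1f, hwe_alpha=%.2f)",
            target_snp_id, window, lod_min, hwe_alpha,
        )
    return SurrogateChoice(target_snp=target_snp_id, chosen=chosen, candidates=df)
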