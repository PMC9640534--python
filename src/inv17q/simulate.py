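"""Synthetic cohort generator providing ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes: an
inversion segregating as two non-recombining haplotype lineages (H2 minor,
frequency ~0.159 as in Polish data), a block of indicator SNPs that
deterministically tag the diplotype (plus independent noise SNPs), per-call
missingness and rare genotyping errors, and a children-count phenotype from a
zero-inflated negative-binomial process with genotype and age effects.
Default effect sizes are those estimated from the real cohort; sex has no
simulated effect.  All randomness flows from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from inv17q.genotype_io import (
    MISSING,
    GenotypeMatrix,
    SnpRecord,
    write_ped_map,
    write_phenotypes,
)

BASES = np.array(list("ACGT"))

DIPLOTYPE_NAMES = {0: "H1_H1", 1: "H1_H2", 2: "H2_H2"}

#: observed composition of small family sizes (0,1,2,3 children) in the cohort
DEFAULT_NONEVENT_COUNTS = (1713, 1051, 1641, 747)


@dataclass
class SimConfig:
    n_subjects: int = 5470
    q_h2: float = 0.159
    n_indicator_snps: int = 22
    n_noise_snps: int = 77
    chrom: str = "17"
    region_start: int = 43_793_582
    region_end: int = 44_776_837
    missing_rate: float = 0.02
    genotype_error_rate: float = 0.001
    age_min: int = 45
    age_max: int = 90
    female_fraction: float = 0.5
    # count part (log link), reference = H2-homozygote class (CC at the tag
    # SNP): beta_ct = heterozygote effect, beta_tt = H1-homozygote effect
    beta0: float = 1.986560
    beta_ct: float = -0.508373
    beta_tt: float = -0.557395
    # zero part (logit link)
    gamma0: float = 3.906649
    gamma_age: float = -0.027448
    theta: float = 1e6  # effectively Poisson, as estimated from the real data
    nonevent_dist: tuple[float, ...] = DEFAULT_NONEVENT_COUNTS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_h2 <= 1.0:
            raise ValueError("q_h2 must lie in [0, 1]")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        probs = np.asarray(self.nonevent_dist, dtype=float)
        if (probs < 0).any() or probs.sum() <= 0:
            raise ValueError("nonevent_dist must be nonnegative with positive mass")

    @property
    def nonevent_probs(self) -> np.ndarray:
        p = np.asarray(self.nonevent_dist, dtype=float)
        return p / p.sum()

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimResult:
    config: SimConfig
    gm: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: pd.DataFrame  # subject_id, diplotype, structural_nonevent, latent_count, nci
    diplotypes: np.ndarray  # H2 dosage 0/1/2 per subject
    indicator_ids: list[str] = field(default_factory=list)


def _apply_noise(
    calls: np.ndarray,
    genotype_choices: list[str],
    error_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Genotyping error = replace the true call by a uniformly random *other*
    genotype of the same SNP; then mask calls at the missingness rate."""
    n = len(calls)
    if error_rate > 0:
        err = rng.random(n) < error_rate
        for i in np.flatnonzero(err):
            others = [g for g in genotype_choices if g != calls[i]]
            calls[i] = others[rng.integers(len(others))]
    if missing_rate > 0:
        calls[rng.random(n) < missing_rate] = MISSING
    return calls


def simulate_haplotypes(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, GenotypeMatrix, list[str]]:
    """Draw diplotypes under Hardy-Weinberg and build the genotype matrix.

    Each subject draws two haplotypes i.i.d. Bernoulli(q_h2).  Indicator SNPs
    carry distinct alleles on the two lineages and reflect the diplotype
    exactly before noise; noise SNPs have random allele frequencies
    independent of the inversion.  Positions are uniform in the region and
    sorted.  Returns (H2 dosage per subject, genotype matrix, indicator ids).
    """
    rng = cfg.rng() if rng is None else rng
    n = cfg.n_subjects
    diplotypes = rng.binomial(2, cfg.q_h2, size=n)
    n_snps = cfg.n_indicator_snps + cfg.n_noise_snps
    positions = np.sort(
        rng.choice(
            np.arange(cfg.region_start, cfg.region_end + 1), size=n_snps, replace=False
        )
    )
    indicator_slots = np.sort(rng.choice(n_snps, size=cfg.n_indicator_snps, replace=False))
    is_indicator = np.zeros(n_snps, dtype=bool)
    is_indicator[indicator_slots] = True

    subjects = [f"S{i + 1:05d}" for i in range(n)]
    snps: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    indicator_ids: list[str] = []
    k_ind = 0
    k_noise = 0
    for j in range(n_snps):
        if is_indicator[j]:
            k_ind += 1
            snp_id = f"ind{k_ind:03d}"
            a1, a2 = rng.choice(BASES, size=2, replace=False)
            genos = np.array([a1 + a1, "".join(sorted(a1 + a2)), a2 + a2], dtype="<U2")
            calls = genos[diplotypes].copy()
            indicator_ids.append(snp_id)
        else:
            k_noise += 1
            snp_id = f"noise{k_noise:03d}"
            a1, a2 = rng.choice(BASES, size=2, replace=False)
            maf = rng.uniform(0.05, 0.5)
            dosage = rng.binomial(2, maf, size=n)
            genos = np.array([a1 + a1, "".join(sorted(a1 + a2)), a2 + a2], dtype="<U2")
            calls = genos[dosage].copy()
        calls = _apply_noise(
            calls, list(genos), cfg.genotype_error_rate, cfg.missing_rate, rng
        )
        seen = sorted({b for g in calls if g != MISSING for b in g})
        snps.append(
            SnpRecord(
                snp_id=snp_id,
                chrom=cfg.chrom,
                pos=int(positions[j]),
                allele_a=seen[0] if seen else None,
                allele_b=seen[1] if len(seen) > 1 else None,
            )
        )
        columns.append(calls)

    calls = (
        np.column_stack(columns) if columns else np.empty((n, 0), dtype="<U2")
    )
    gm = GenotypeMatrix(subjects=subjects, snps=snps, calls=calls)
    return diplotypes, gm, indicator_ids


def simulate_demographics(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Ages uniform integer in [age_min, age_max]; sex 1=female, 2=male."""
    rng = cfg.rng() if rng is None else rng
    ages = rng.integers(cfg.age_min, cfg.age_max + 1, size=cfg.n_subjects)
    sexes = np.where(rng.random(cfg.n_subjects) < cfg.female_fraction, 1, 2)
    return ages, sexes


def simulate_nci(
    cfg: SimConfig,
    diplotypes: np.ndarray,
    ages: np.ndarray,
    sexes: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Children counts from the zero-inflated generative process.

    With probability pi_i = logistic(gamma0 + gamma_age * age) the subject is
    a structural non-event and draws NCI from the observed 0-3 composition;
    otherwise NCI ~ NB(mu_i, theta) with log mu_i = beta0 + beta_ct 1{het} +
    beta_tt 1{H1-hom} — the H2-homozygote class is the reference, as in the
    published coefficient table, so H2 homozygotes have the largest mean.
    Count draws <= 3 simply land in the non-event band on recoding,
    mirroring the fitted model's mixture.  Sex has no effect.
    """
    rng = cfg.rng() if rng is None else rng
    diplotypes = np.asarray(diplotypes)
    n = len(diplotypes)
    ages = np.asarray(ages, dtype=float)
    pi = special.expit(cfg.gamma0 + cfg.gamma_age * ages)
    structural = rng.random(n) < pi
    eta = cfg.beta0 + cfg.beta_ct * (diplotypes == 1) + cfg.beta_tt * (diplotypes == 0)
    mu = np.exp(eta)
    latent = rng.negative_binomial(cfg.theta, cfg.theta / (cfg.theta + mu))
    small = rng.choice(4, size=n, p=cfg.nonevent_probs)
    nci = np.where(structural, small, latent)
    truth = pd.DataFrame(
        {
            "diplotype": [DIPLOTYPE_NAMES[d] for d in diplotypes],
            "structural_nonevent": structural.astype(int),
            "latent_count": latent,
            "nci": nci,
        }
    )
    return nci, truth


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Full cohort: genotypes, demographics, children counts and truth table."""
    rng = cfg.rng()
    diplotypes, gm, indicator_ids = simulate_haplotypes(cfg, rng)
    ages, sexes = simulate_demographics(cfg, rng)
    nci, truth = simulate_nci(cfg, diplotypes, ages, sexes, rng)
    pheno = pd.DataFrame(
        {
            "subject_id": gm.subjects,
            "sex": sexes,
            "age": ages,
            "nci": nci,
            "county": [""] * cfg.n_subjects,
        }
    )
    truth.insert(0, "subject_id", gm.subjects)
    return SimResult(
        config=cfg,
        gm=gm,
        phenotypes=pheno,
        truth=truth,
        diplotypes=diplotypes,
        indicator_ids=indicator_ids,
    )


def simulate_ld_pair(
    n: int,
    p_AB: float,
    p_Ab: float,
    p_aB: float,
    p_ab: float,
    seed: int | np.random.Generator = 0,
):
    """Unphased 3x3 genotype counts from known haplotype frequencies: each
    subject draws two haplotypes i.i.d. from the four-haplotype distribution."""
    from inv17q.ld import TwoLocusCounts

    freqs = np.array([p_AB, p_Ab, p_aB, p_ab], dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("haplotype frequencies must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dosage_a = np.array([0, 0, 1, 1])
    dosage_b = np.array([0, 1, 0, 1])
    h1 = rng.choice(4, size=n, p=freqs)
    h2 = rng.choice(4, size=n, p=freqs)
    i = dosage_a[h1] + dosage_a[h2]
    j = dosage_b[h1] + dosage_b[h2]
    table = np.zeros((3, 3))
    np.add.at(table, (i, j), 1)
    return TwoLocusCounts(table=table)


def simulate_zinb_response(
    X: np.ndarray,
    Z: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
    theta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a response from the exact ZINB likelihood (structural zero with
    probability logistic(Z gamma), else NB(exp(X beta), theta)).

    This is the estimator-validation counterpart of :func:`simulate_nci`:
    the data-generating process coincides with the fitted model, so bias and
    confidence-interval coverage of the fit are interpretable.
    """
    n = X.shape[0]
    pi = special.expit(Z @ gamma)
    mu = np.exp(X @ beta)
    structural = rng.random(n) < pi
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    return np.where(structural, 0, counts)


def write_fixture(cfg: SimConfig, out_dir) -> dict[str, Path]:
    """Write PED/MAP, phenotype TSV and truth TSV; byte-identical per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_dataset(cfg)
    paths = {
        "ped": out / "genotypes.ped",
        "map": out / "genotypes.map",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.tsv",
    }
    write_ped_map(sim.gm, paths["ped"], paths["map"], pheno=sim.phenotypes)
    write_phenotypes(sim.phenotypes, paths["phenotypes"])
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
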