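"""Inversion diplotype calling from unphased tag-SNP genotypes.

The 17q21.31 inversion suppresses recombination between its two orientations,
so within the inverted interval every "indicator" SNP splits subjects into the
same three classes: homozygous for the H1-lineage allele, heterozygous, and
homozygous for the H2-lineage allele.  The caller exploits this: it seeds a
3-way subject partition from the highest-coverage SNPs that induce identical
partitions, admits further SNPs whose genotype classes respect the partition
(up to a small tolerated number of discordant subjects, attributed to
post-divergence mutation or genotyping error), and then assigns every subject
to the closest group consensus over the indicator SNPs.  The largest
homozygous group is labelled H1_H1 — H2 is the minor lineage in all surveyed
populations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from inv17q.genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

H1_H1 = "H1_H1"
H1_H2 = "H1_H2"
H2_H2 = "H2_H2"
UNASSIGNED = "UNASSIGNED"


class SeedCoverageError(RuntimeError):
    """No SNP meets the seeding coverage threshold; relax ``min_coverage``."""


@dataclass
class Partition3:
    """Disjoint candidate groups: homozygous-major, heterozygous, homozygous-minor."""

    group1: set[str]
    group2: set[str]
    group3: set[str]

    def __post_init__(self) -> None:
        if (self.group1 & self.group2) or (self.group1 & self.group3) or (self.group2 & self.group3):
            raise ValueError("partition groups must be pairwise disjoint")

    @property
    def assigned(self) -> set[str]:
        return self.group1 | self.group2 | self.group3


@dataclass
class IndicatorSet:
    """Indicator SNPs with, per SNP, the H1- and H2-tagging alleles."""

    snp_ids: list[str]
    h1_allele: dict[str, str]
    h2_allele: dict[str, str]  # orientation: allele carried by the H2 lineage

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class InversionCallResult:
    labels: dict[str, str]  # subject -> H1_H1 / H1_H2 / H2_H2 / UNASSIGNED
    mismatches: dict[str, int]  # discordant indicator calls vs best-fit group
    best_score: dict[str, float]
    indicator_set: IndicatorSet
    representative_snp: str | None
    group_sizes: dict[str, int] = field(default_factory=dict)

    def labels_array(self, subjects: list[str]) -> np.ndarray:
        return np.array([self.labels[s] for s in subjects])

    def to_json(self) -> str:
        return json.dumps(
            {
                "indicator_snps": self.indicator_set.snp_ids,
                "h1_allele": self.indicator_set.h1_allele,
                "h2_allele": self.indicator_set.h2_allele,
                "representative_snp": self.representative_snp,
                "group_sizes": self.group_sizes,
            },
            indent=2,
        )


def _snp_class_labels(col: np.ndarray) -> np.ndarray | None:
    """Label a genotype column 0/1/2 = hom-major/het/hom-minor, -1 = missing.

    Returns None when the column has no heterozygotes or more than two
    alleles (not usable for a 3-way split).
    """
    n = len(col)
    labels = np.full(n, -1, dtype=np.int8)
    alleles: dict[str, int] = {}
    for g in col:
        if g == MISSING:
            continue
        for b in g:
            alleles[b] = alleles.get(b, 0) + 1
    if len(alleles) != 2:
        return None
    a_major, a_minor = sorted(alleles, key=lambda a: (-alleles[a], a))
    hom_major, het, hom_minor = a_major * 2, "".join(sorted(a_major + a_minor)), a_minor * 2
    for i, g in enumerate(col):
        if g == MISSING:
            continue
        if g == hom_major:
            labels[i] = 0
        elif g == het:
            labels[i] = 1
        elif g == hom_minor:
            labels[i] = 2
        else:
            return None  # third allele present
    return labels


def _concordant(a: np.ndarray, b: np.ndarray, tol_frac: float = 0.0) -> tuple[bool, bool]:
    """Compare two label vectors on common non-missing subjects, directly or
    with homozygote classes swapped (allele relabeling).

    Returns (concordant, swapped); disagreement on up to ``tol_frac`` of the
    compared subjects is tolerated (genotyping error / post-divergence
    mutation, observed at roughly 10/5470 per SNP in real data).
    """
    common = (a >= 0) & (b >= 0)
    n_common = int(common.sum())
    if n_common == 0:
        return False, False
    av, bv = a[common], b[common]
    direct = int(np.sum(av != bv))
    swapped = int(np.sum(av != 2 - bv))
    tol = int(np.ceil(tol_frac * n_common))
    if min(direct, swapped) > tol:
        return False, False
    return True, swapped < direct


def seed_partition(
    gm: GenotypeMatrix,
    min_coverage: float = 1.0,
    min_group_frac: float = 0.01,
    seed_discordance_frac: float = 0.005,
) -> tuple[Partition3, list[str]]:
    """Seed the 3-way subject partition from high-coverage SNPs.

    SNPs with call rate >= ``min_coverage`` are clustered by the partition
    they induce (identical up to allele relabeling on shared non-missing
    subjects, tolerating discordance on up to ``seed_discordance_frac`` of
    the compared subjects per pair); the largest cluster defines the seed groups by per-subject
    majority over its SNPs.  Candidate groups holding fewer than
    ``min_group_frac`` of subjects are not treated as major categories:
    their members are left out of the seed partition and picked up later by
    maximum-similarity assignment.

    group1 is the larger homozygous class.  Raises :class:`SeedCoverageError`
    when no SNP reaches the coverage threshold.
    """
    n = gm.n_subjects
    cand: list[tuple[int, np.ndarray]] = []
    for j in range(gm.n_snps):
        if gm.call_rate(j) >= min_coverage:
            labels = _snp_class_labels(gm.calls[:, j])
            if labels is not None and (labels == 1).any():
                cand.append((j, labels))
    if not cand:
        raise SeedCoverageError(
            f"no usable SNP with call rate >= {min_coverage}; "
            "relax min_coverage to seed the partition"
        )
    # highest coverage first, position as deterministic tie-break
    cand.sort(key=lambda jl: (-float(np.mean(jl[1] >= 0)), gm.snps[jl[0]].pos))

    clusters: list[list[tuple[int, np.ndarray]]] = []
    for j, labels in cand:
        placed = False
        for cl in clusters:
            ref = cl[0][1]
            ok, swapped = _concordant(labels, ref, tol_frac=seed_discordance_frac)
            if ok:
                if swapped:
                    labels = 2 - labels  # orient to cluster reference
                    labels[labels == 3] = -1
                cl.append((j, labels))
                placed = True
                break
        if not placed:
            clusters.append([(j, labels)])
    best = max(clusters, key=len)
    seed_ids = [gm.snps[j].snp_id for j, _ in best]

    # majority label per subject over the cluster's SNPs
    stack = np.stack([labels for _, labels in best])
    groups: list[set[str]] = [set(), set(), set()]
    for i, sid in enumerate(gm.subjects):
        col = stack[:, i]
        col = col[col >= 0]
        if len(col) == 0:
            continue
        counts = np.bincount(col, minlength=3)
        groups[int(np.argmax(counts))].add(sid)

    hom_a, het, hom_b = groups
    if len(hom_b) > len(hom_a):
        hom_a, hom_b = hom_b, hom_a
    min_n = max(1, int(np.ceil(min_group_frac * n)))
    if 0 < len(hom_b) < min_n:
        logger.info(
            "seed_partition: homozygous-minor class has %d subjects (<%d); "
            "deferring them to similarity assignment",
            len(hom_b),
            min_n,
        )
        hom_b = set()
    part = Partition3(group1=hom_a, group2=het, group3=hom_b)
    logger.info(
        "seed_partition: %d seed SNPs, groups %d/%d/%d (of %d subjects)",
        len(seed_ids),
        len(part.group1),
        len(part.group2),
        len(part.group3),
        n,
    )
    return part, seed_ids


def find_indicators(
    gm: GenotypeMatrix, part: Partition3, max_discordant: int = 10
) -> IndicatorSet:
    """Admit SNPs whose genotype classes respect the seed partition.

    A SNP qualifies when — ignoring missing data and up to ``max_discordant``
    discordant subjects in total — group1 subjects are homozygous for one
    allele, group2 subjects heterozygous, and group3 subjects homozygous for
    the other allele.  The group3 allele is recorded as H2-tagging; when
    group3 is empty it is inferred as the non-group1 allele seen in
    heterozygotes.
    """
    if not part.group1 or not part.group2:
        raise ValueError("partition must have nonempty homozygous-major and heterozygous groups")
    subj_index = {s: i for i, s in enumerate(gm.subjects)}
    g1 = np.array([subj_index[s] for s in sorted(part.group1)])
    g2 = np.array([subj_index[s] for s in sorted(part.group2)])
    g3 = np.array([subj_index[s] for s in sorted(part.group3)]) if part.group3 else np.array([], dtype=int)

    snp_ids: list[str] = []
    h1_allele: dict[str, str] = {}
    h2_allele: dict[str, str] = {}
    for j, snp in enumerate(gm.snps):
        col = gm.calls[:, j]
        c1 = col[g1]
        c1 = c1[c1 != MISSING]
        if len(c1) == 0:
            continue
        homs, counts = np.unique(c1, return_counts=True)
        modal = homs[np.argmax(counts)]
        if modal[0] != modal[1]:
            continue
        a1 = modal[0]
        # H2 allele from counter-homozygous group, else from heterozygotes
        if len(g3):
            c3 = col[g3]
            c3 = c3[c3 != MISSING]
            if len(c3) == 0:
                continue
            homs3, counts3 = np.unique(c3, return_counts=True)
            modal3 = homs3[np.argmax(counts3)]
            if modal3[0] != modal3[1] or modal3[0] == a1:
                continue
            a2 = modal3[0]
        else:
            c2nm = col[g2]
            c2nm = c2nm[c2nm != MISSING]
            others = {b for g in c2nm for b in g} - {a1}
            if len(others) != 1:
                continue
            a2 = others.pop()
        het = "".join(sorted(a1 + a2))
        discordant = 0
        for idx_arr, expected in ((g1, a1 + a1), (g2, het), (g3, a2 + a2)):
            if len(idx_arr) == 0:
                continue
            sub = col[idx_arr]
            sub = sub[sub != MISSING]
            discordant += int(np.sum(sub != expected))
        if discordant <= max_discordant:
            snp_ids.append(snp.snp_id)
            h1_allele[snp.snp_id] = a1
            h2_allele[snp.snp_id] = a2
    return IndicatorSet(snp_ids=snp_ids, h1_allele=h1_allele, h2_allele=h2_allele)


def assign_subjects(
    gm: GenotypeMatrix, ind: IndicatorSet, part: Partition3
) -> InversionCallResult:
    """Score every subject against the three group consensus genotype vectors
    over the indicator SNPs and assign by maximum similarity.

    The consensus at an indicator SNP follows its orientation: group1 is
    homozygous H1-allele, group2 heterozygous, group3 homozygous H2-allele.
    Ties and all-missing subjects are left UNASSIGNED.  After assignment the
    larger homozygous group receives the H1_H1 label.
    """
    if not ind.snp_ids:
        raise ValueError("empty indicator set")
    cols = [gm.snp_index(sid) for sid in ind.snp_ids]
    consensus = np.empty((3, len(cols)), dtype="<U2")
    for k, sid in enumerate(ind.snp_ids):
        a1, a2 = ind.h1_allele[sid], ind.h2_allele[sid]
        consensus[0, k] = a1 + a1
        consensus[1, k] = "".join(sorted(a1 + a2))
        consensus[2, k] = a2 + a2

    calls = gm.calls[:, cols]
    nonmiss = calls != MISSING
    scores = np.zeros((gm.n_subjects, 3))
    matches = np.zeros((gm.n_subjects, 3), dtype=int)
    for g in range(3):
        eq = (calls == consensus[g][None, :]) & nonmiss
        matches[:, g] = eq.sum(axis=1)
    n_comp = nonmiss.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(n_comp[:, None] > 0, matches / np.maximum(n_comp, 1)[:, None], 0.0)

    raw_labels = np.full(gm.n_subjects, -1, dtype=int)
    for i in range(gm.n_subjects):
        if n_comp[i] == 0:
            continue
        best = np.max(scores[i])
        winners = np.flatnonzero(scores[i] == best)
        if len(winners) == 1:
            raw_labels[i] = winners[0]

    # H1_H1 = larger homozygous group after assignment
    n_hom0 = int(np.sum(raw_labels == 0))
    n_hom2 = int(np.sum(raw_labels == 2))
    if n_hom2 > n_hom0:
        name_of = {0: H2_H2, 1: H1_H2, 2: H1_H1}
    else:
        name_of = {0: H1_H1, 1: H1_H2, 2: H2_H2}

    labels: dict[str, str] = {}
    mism: dict[str, int] = {}
    best_score: dict[str, float] = {}
    for i, sid in enumerate(gm.subjects):
        if raw_labels[i] < 0:
            labels[sid] = UNASSIGNED
            mism[sid] = int(n_comp[i])
            best_score[sid] = 0.0
        else:
            g = raw_labels[i]
            labels[sid] = name_of[g]
            mism[sid] = int(n_comp[i] - matches[i, g])
            best_score[sid] = float(scores[i, g])

    sizes = {lab: 0 for lab in (H1_H1, H1_H2, H2_H2, UNASSIGNED)}
    for lab in labels.values():
        sizes[lab] += 1
    rep = pick_representative(ind, gm)
    return InversionCallResult(
        labels=labels,
        mismatches=mism,
        best_score=best_score,
        indicator_set=ind,
        representative_snp=rep,
        group_sizes=sizes,
    )


def pick_representative(ind: IndicatorSet, gm: GenotypeMatrix) -> str:
    """Indicator SNP with maximal call rate; ties broken by smallest position."""
    if not ind.snp_ids:
        raise ValueError("empty indicator set")
    best_id, best_key = None, None
    for sid in ind.snp_ids:
        j = gm.snp_index(sid)
        key = (-gm.call_rate(j), gm.snps[j].pos)
        if best_key is None or key < best_key:
            best_id, best_key = sid, key
    return best_id


def h2_frequency(res: InversionCallResult) -> float:
    """H2 allele frequency among assigned subjects: (2 n_H2H2 + n_H1H2) / (2 n)."""
    n11 = res.group_sizes.get(H1_H1, 0)
    n12 = res.group_sizes.get(H1_H2, 0)
    n22 = res.group_sizes.get(H2_H2, 0)
    n = n11 + n12 + n22
    if n == 0:
        raise ValueError("no assigned subjects; H2 frequency undefined")
    return (2 * n22 + n12) / (2 * n)


def call_inversion(
    gm: GenotypeMatrix,
    min_coverage: float = 1.0,
    max_discordant: int = 10,
    min_group_frac: float = 0.01,
) -> InversionCallResult:
    """Full calling pass: seed partition, indicator discovery, assignment.

    When no SNP has full coverage, the seeding threshold is relaxed to admit
    the ~25 highest-coverage SNPs; the partition clustering then isolates
    the non-recombinant block from unlinked markers.
    """
    try:
        part, _seed = seed_partition(
            gm, min_coverage=min_coverage, min_group_frac=min_group_frac
        )
    except SeedCoverageError:
        rates = sorted((gm.call_rate(j) for j in range(gm.n_snps)), reverse=True)
        relaxed = rates[min(24, len(rates) - 1)]
        logger.warning(
            "call_inversion: no full-coverage SNP; relaxing seed threshold to %.4f", relaxed
        )
        part, _seed = seed_partition(
            gm, min_coverage=relaxed, min_group_frac=min_group_frac
        )
    ind = find_indicators(gm, part, max_discordant=max_discordant)
    return assign_subjects(gm, ind, part)
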