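"""End-to-end orchestration and descriptive statistics.

The full analysis chain is: read (or simulate) genotypes and phenotypes ->
marker QC -> region slice -> completed-family age filter -> inversion
diplotype calling -> representative-SNP cross-tabulation and dominance /
recessive contrasts -> age-bin weights -> interaction-pruned weighted ZINB ->
term tests and Bonferroni decision -> optional surrogate selection and
negative-control scan.  Every stage logs subject/SNP counts; a stage failure
marks the report but preserves earlier results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from inv17q import caller, genotype_io, ld, zinb
from inv17q.genotype_io import MISSING, GenotypeMatrix, SnpRecord
from inv17q.simulate import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)

#: inversion region between the flanking microsatellite anchors (GRCh37)
INVERSION_REGION = ("17", 43_488_002, 44_857_562)
CONTROL_EXCLUDED_CHROMS = ("1", "5", "14", "X", "Y")


# --- descriptive statistics ----------------------------------------------

def _infer_class_order(classes: list[str], counts: dict[str, int]) -> tuple[str, str, str]:
    """(hom_minor, het, hom_major) from genotype-style or diplotype labels."""
    def looks_het(c: str) -> bool:
        return (len(c) == 2 and c[0] != c[1]) or c == "H1_H2"

    hets = [c for c in classes if looks_het(c)]
    homs = [c for c in classes if not looks_het(c)]
    if len(hets) != 1 or len(homs) != 2:
        raise ValueError(f"cannot infer genotype class roles from {classes}")
    homs.sort(key=lambda c: counts[c])
    return homs[0], hets[0], homs[1]


def crosstab_nci(
    genotype_labels: np.ndarray,
    nci: np.ndarray,
    class_order: tuple[str, str, str] | None = None,
    allele_names: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Genotype x NCI count table with derived combination and allele rows.

    Rows: hom-minor, het, hom-major, het+hom-major, hom-minor+het, and the
    two allele-dosage rows (each homozygote contributes 2, each heterozygote
    1 to its alleles).  ``class_order`` = (hom_minor, het, hom_major); when
    omitted it is inferred from the labels (minor = smaller homozygote class).
    """
    genotype_labels = np.asarray(genotype_labels).astype(str)
    nci = np.asarray(nci).astype(int)
    if np.any(nci < 0):
        raise ValueError("negative children counts")
    classes, cls_counts = np.unique(genotype_labels, return_counts=True)
    counts_by_class = dict(zip(classes.tolist(), cls_counts.tolist()))
    if class_order is None:
        class_order = _infer_class_order(list(classes), counts_by_class)
    hom_minor, het, hom_major = class_order
    max_nci = int(nci.max()) if len(nci) else 0
    cols = np.arange(max_nci + 1)
    base = pd.DataFrame(0, index=[hom_minor, het, hom_major], columns=cols)
    for cls in class_order:
        vals, n = np.unique(nci[genotype_labels == cls], return_counts=True)
        base.loc[cls, vals] = n
    return add_derived_rows(base, class_order, allele_names)


def add_derived_rows(
    base: pd.DataFrame,
    class_order: tuple[str, str, str],
    allele_names: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Append combination rows and allele-dosage rows to a 3-row crosstab."""
    hom_minor, het, hom_major = class_order
    if allele_names is None:
        if all(len(c) == 2 for c in class_order):
            allele_names = (hom_minor[0], hom_major[0])
        else:
            allele_names = ("H2", "H1")
    minor_allele, major_allele = allele_names
    out = base.loc[[hom_minor, het, hom_major]].copy()
    out.loc[f"{het}+{hom_major}"] = base.loc[het] + base.loc[hom_major]
    out.loc[f"{hom_minor}+{het}"] = base.loc[hom_minor] + base.loc[het]
    out.loc[f"allele_{minor_allele}"] = 2 * base.loc[hom_minor] + base.loc[het]
    out.loc[f"allele_{major_allele}"] = 2 * base.loc[hom_major] + base.loc[het]
    out.index.name = "group"
    return out


def group_mean_nci(row: pd.Series | np.ndarray) -> float:
    """Mean children count of a crosstab row: sum(k * n_k) / sum(n_k)."""
    row = pd.Series(row)
    total = row.sum()
    if total <= 0:
        raise ValueError("empty count row; mean undefined")
    k = np.asarray(row.index, dtype=float)
    return float(np.dot(k, row.to_numpy()) / total)


def dominance_contrasts(
    table: pd.DataFrame, class_order: tuple[str, str, str], display_dp: int = 3
) -> dict[str, float]:
    """Recessive and dominant descriptive contrasts of mean children counts.

    recessive = mean(hom-minor) - mean(het u hom-major); dominant =
    mean(hom-minor u het) - mean(hom-major).  The ``*_display`` variants
    first round each group mean to ``display_dp`` decimals and then subtract
    (the arithmetic used when quoting rounded tables).
    """
    hom_minor, het, hom_major = class_order
    for cls in class_order:
        if table.loc[cls].sum() <= 0:
            raise ValueError(f"empty genotype class {cls!r}")
    m_minor = group_mean_nci(table.loc[hom_minor])
    m_major = group_mean_nci(table.loc[hom_major])
    m_rest = group_mean_nci(table.loc[het] + table.loc[hom_major])
    m_carrier = group_mean_nci(table.loc[hom_minor] + table.loc[het])
    r = display_dp
    return {
        "recessive_diff": m_minor - m_rest,
        "dominant_diff": m_carrier - m_major,
        "recessive_diff_display": round(round(m_minor, r) - round(m_rest, r), r),
        "dominant_diff_display": round(round(m_carrier, r) - round(m_major, r), r),
    }


# --- negative controls ---------------------------------------------------

def sample_negative_controls(
    snps: list[SnpRecord],
    n_target: int = 200,
    seed: int | np.random.Generator = 0,
    gm: GenotypeMatrix | None = None,
    excluded_chroms: tuple[str, ...] = CONTROL_EXCLUDED_CHROMS,
    excluded_region: tuple[str, int, int] = INVERSION_REGION,
) -> list[str]:
    """Random negative-control SNP ids.

    Draws ``n_target`` ids uniformly without replacement, then applies the
    exclusions in order: study chromosomes and the inversion region, then —
    when genotypes are supplied — SNPs without all three genotype classes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = [s.snp_id for s in snps]
    by_id = {s.snp_id: s for s in snps}
    n_draw = min(n_target, len(ids))
    drawn = list(rng.choice(ids, size=n_draw, replace=False))
    survivors: list[str] = []
    rchrom, rstart, rend = excluded_region
    for sid in drawn:
        s = by_id[sid]
        if str(s.chrom) in excluded_chroms:
            continue
        if str(s.chrom) == str(rchrom) and rstart <= s.pos <= rend:
            continue
        if gm is not None:
            j = gm.snp_index(sid)
            col = gm.calls[:, j]
            if len(set(col[col != MISSING])) < 3:
                continue
        survivors.append(sid)
    if not survivors:
        raise ValueError("no negative-control SNP survived the exclusions")
    return survivors


# --- full pipeline -------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration for :func:`run_full_analysis` (YAML-mappable)."""

    ped_path: str | None = None
    map_path: str | None = None
    phenotype_path: str | None = None
    sim: SimConfig | None = None  # used when no paths are given
    region: tuple[str, int, int] | None = None
    min_call_rate: float = 0.75
    min_maf: float = 0.01
    min_age_female: int = 45
    min_age_male: int = 55
    nonevent_threshold: int = 3
    interaction_alpha: float = 0.05
    bonferroni_m: int = 7
    max_discordant: int = 10
    seed: int = 0
    run_controls: bool = False
    n_control_target: int = 200

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        if cfg.region is not None:
            cfg.region = tuple(cfg.region)  # type: ignore[assignment]
        return cfg


@dataclass
class AnalysisReport:
    stage_counts: list[dict[str, Any]] = field(default_factory=list)
    failed_stages: dict[str, str] = field(default_factory=dict)
    table1: pd.DataFrame | None = None
    group_means: dict[str, float] = field(default_factory=dict)
    contrasts: dict[str, float] = field(default_factory=dict)
    group_sizes: dict[str, int] = field(default_factory=dict)
    h2_frequency: float | None = None
    representative_snp: str | None = None
    indicator_snps: list[str] = field(default_factory=list)
    fit_summary: pd.DataFrame | None = None
    term_table: pd.DataFrame | None = None
    interactions_kept: bool | None = None
    overdispersed: bool | None = None
    overdispersion_p: float | None = None
    bonferroni_m: int = 7
    snp_term_p: float | None = None
    snp_significant_bonferroni: bool | None = None
    model_status: str = "not_run"
    control_summary: dict[str, Any] = field(default_factory=dict)
    metadata: dict[str, Any] = field(default_factory=dict)

    def log_stage(self, stage: str, n_subjects: int, n_snps: int) -> None:
        logger.info("stage %-22s subjects=%-6d snps=%d", stage, n_subjects, n_snps)
        self.stage_counts.append({"stage": stage, "n_subjects": n_subjects, "n_snps": n_snps})

    def to_json(self, indent: int = 2) -> str:
        def conv(obj):
            if isinstance(obj, pd.DataFrame):
                return obj.reset_index().to_dict(orient="records")
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        payload = {
            k: conv(v)
            for k, v in self.__dict__.items()
        }
        return json.dumps(payload, indent=indent, default=str)


def run_full_analysis(config: PipelineConfig) -> AnalysisReport:
    """Execute the full association pipeline and return the report.

    Stage failures are recorded in ``report.failed_stages`` and leave earlier
    results intact; a representative SNP without three genotype classes
    yields ``model_status = "model not formed"`` rather than an error.
    """
    report = AnalysisReport(bonferroni_m=config.bonferroni_m)
    report.metadata = {"seed": config.seed, "config": str(config)}

    # -- load or simulate
    if config.ped_path is not None:
        gm, _ = genotype_io.read_ped_map(config.ped_path, config.map_path)
        pheno = genotype_io.read_phenotypes(config.phenotype_path)
    else:
        sim_cfg = config.sim if config.sim is not None else SimConfig(seed=config.seed)
        sim = simulate_dataset(sim_cfg)
        gm, pheno = sim.gm, sim.phenotypes
        report.metadata["simulated"] = True
    report.log_stage("input", gm.n_subjects, gm.n_snps)

    # -- marker QC
    gm, filt = genotype_io.filter_snps(gm, config.min_call_rate, config.min_maf)
    report.metadata["filter_report"] = {
        "n_input": filt.n_input,
        "indel": filt.n_excluded_indel,
        "monomorphic": filt.n_excluded_monomorphic,
        "low_call_rate": filt.n_excluded_lowcall,
        "low_maf": filt.n_excluded_maf,
        "kept": filt.n_kept,
    }
    report.log_stage("snp_qc", gm.n_subjects, gm.n_snps)

    if config.region is not None:
        gm = genotype_io.region_slice(gm, *config.region)
        report.log_stage("region_slice", gm.n_subjects, gm.n_snps)

    # -- completed-family age filter
    pheno = genotype_io.filter_age_range(pheno, config.min_age_female, config.min_age_male)
    gm = gm.take_subjects(pheno["subject_id"].tolist())
    pheno = pheno.set_index("subject_id").loc[gm.subjects].reset_index()
    report.log_stage("age_filter", gm.n_subjects, gm.n_snps)

    # -- inversion calling
    try:
        call = caller.call_inversion(gm, max_discordant=config.max_discordant)
    except Exception as exc:  # noqa: BLE001 - stage isolation
        report.failed_stages["inversion_call"] = str(exc)
        return report
    report.group_sizes = call.group_sizes
    report.indicator_snps = call.indicator_set.snp_ids
    report.representative_snp = call.representative_snp
    try:
        report.h2_frequency = caller.h2_frequency(call)
    except ValueError as exc:
        report.failed_stages["h2_frequency"] = str(exc)
    report.log_stage("inversion_call", gm.n_subjects, len(call.indicator_set))

    # -- representative-SNP genotype labels for descriptives and regression
    j_rep = gm.snp_index(call.representative_snp)
    rep_calls = gm.calls[:, j_rep]
    keep = rep_calls != MISSING
    labels = rep_calls[keep]
    sub = pheno.loc[keep.tolist()].reset_index(drop=True)
    nci = sub["nci"].to_numpy(dtype=int)
    report.log_stage("representative_snp", int(keep.sum()), 1)

    try:
        classes = np.unique(labels)
        if len(classes) < 3:
            raise zinb.ModelNotFormedError(
                f"representative SNP has {len(classes)} genotype classes"
            )
        cls_counts = {c: int(np.sum(labels == c)) for c in classes}
        order = _infer_class_order(list(classes), cls_counts)
        table = crosstab_nci(labels, nci, class_order=order)
        report.table1 = table
        report.group_means = {str(g): group_mean_nci(table.loc[g]) for g in table.index}
        report.contrasts = dominance_contrasts(table, order)
    except (ValueError, zinb.ModelNotFormedError) as exc:
        report.failed_stages["descriptives"] = str(exc)

    # -- weighted ZINB with interaction pruning
    try:
        if len(np.unique(labels)) < 3:
            raise zinb.ModelNotFormedError(
                "representative SNP lacks all three genotype classes"
            )
        weights = zinb.age_bin_weights(sub["age"].to_numpy())
        fit, kept = zinb.prune_interactions(
            labels,
            sub["age"].to_numpy(dtype=float),
            sub["sex"].to_numpy(dtype=float),
            nci,
            weights=weights,
            threshold=config.nonevent_threshold,
            alpha=config.interaction_alpha,
        )
        report.interactions_kept = kept
        report.fit_summary = fit.summary_frame()
        report.term_table = zinb.term_tests(fit)
        over, p_over, note = zinb.overdispersion_check(fit)
        report.overdispersed = over
        report.overdispersion_p = p_over
        if note:
            report.metadata["overdispersion_note"] = note
        snp_row = report.term_table[report.term_table["term"] == "SNP"]
        if len(snp_row):
            report.snp_term_p = float(snp_row["p"].iloc[0])
            report.snp_significant_bonferroni = zinb.bonferroni(
                [report.snp_term_p], m=config.bonferroni_m
            )[0]
        report.model_status = "ok" if fit.converged else "not converged"
    except zinb.ModelNotFormedError as exc:
        report.model_status = "model not formed"
        report.failed_stages["zinb"] = str(exc)
    except Exception as exc:  # noqa: BLE001 - stage isolation
        report.model_status = "failed"
        report.failed_stages["zinb"] = str(exc)

    # -- negative controls (optional; requires off-region markers)
    if config.run_controls:
        try:
            control_ids = sample_negative_controls(
                gm.snps, n_target=config.n_control_target, seed=config.seed, gm=gm
            )
            results = control_snp_scan(
                gm, sub, control_ids, weights=None, threshold=config.nonevent_threshold
            )
            report.control_summary = results
        except Exception as exc:  # noqa: BLE001
            report.failed_stages["negative_controls"] = str(exc)

    return report


def control_snp_scan(
    gm: GenotypeMatrix,
    pheno: pd.DataFrame,
    snp_ids: list[str],
    weights: np.ndarray | None = None,
    threshold: int = 3,
    alpha: float = 0.05,
) -> dict[str, Any]:
    """Fit the main-effects ZINB per control SNP; summarize rejections at
    ``alpha`` and SNPs that failed to form a model."""
    n_sig = 0
    n_formed = 0
    not_formed: list[str] = []
    pvals: dict[str, float] = {}
    for sid in snp_ids:
        j = gm.snp_index(sid)
        col = gm.calls[:, j]
        keep = col != MISSING
        sub = pheno.loc[keep.tolist()]
        try:
            w = zinb.age_bin_weights(sub["age"].to_numpy()) if weights is None else weights[keep]
            spec = zinb.build_design(
                col[keep],
                sub["age"].to_numpy(dtype=float),
                sub["sex"].to_numpy(dtype=float),
                sub["nci"].to_numpy(dtype=int),
                weights=w,
                threshold=threshold,
            )
            if len(spec.term_blocks["SNP"]) < 2:
                raise zinb.ModelNotFormedError("fewer than three genotype classes")
            fit = zinb.fit_zinb(spec)
            tt = zinb.term_tests(fit)
            p = float(tt.loc[tt["term"] == "SNP", "p"].iloc[0])
            pvals[sid] = p
            n_formed += 1
            if p < alpha:
                n_sig += 1
        except (zinb.ModelNotFormedError, FloatingPointError) as exc:
            not_formed.append(sid)
            logger.info("control SNP %s: model not formed (%s)", sid, exc)
    return {
        "n_tested": len(snp_ids),
        "n_formed": n_formed,
        "n_significant": n_sig,
        "not_formed": not_formed,
        "p_values": pvals,
    }
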