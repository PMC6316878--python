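"""End-to-end orchestration of the two study phases.

Testing phase: QC filter cascade -> per-variant association on both
endpoints with permutation-adjusted p-values (survival permuted within
therapy arm) -> gene-dosage gate -> evidence integration -> ranked
validation panel.

Validation phase: panel variants are re-tested in the validation cohort
(genotype-group collapsing, chi-square + logistic adjustment for response,
log-rank + Cox adjustment for survival, per-subtype log-rank), the dosage
gate is re-applied, and variants significant in both phases that stay
dosage-consistent are flagged validated.

Each stage logs variant in/out counts so the prioritization funnel can be
reconstructed from the run log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import dosage_gate, prioritize, qc, variant_io
from .variant_io import ClinicalTable, GenotypeMatrix

logger = logging.getLogger("pharmprio.pipeline")

CYTOTOXIC_ARMS = ("neoadjuvant", "adjuvant")


@dataclass
class RunConfig:
    phase: str = "testing"
    genotypes_path: str | None = None
    genotypes_format: str = "tsv"
    clinical_path: str | None = None
    evidence_path: str | None = None
    panel_path: str | None = None
    out_dir: str = "."
    thresholds: qc.QcThresholds = field(default_factory=qc.QcThresholds)
    response_permutations: int = assoc.DEFAULT_RESPONSE_PERMUTATIONS
    survival_permutations: int = assoc.DEFAULT_SURVIVAL_PERMUTATIONS
    dfs_horizon: float = assoc.DFS_HORIZON_MONTHS
    alpha: float = 0.05
    response_covariates: tuple[str, ...] = ("stage",)
    survival_covariates: tuple[str, ...] = ("grade", "stage", "er", "pr")
    max_panel_size: int = 58
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase not in ("testing", "validation"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg = replace(cfg, thresholds=qc.QcThresholds(**thr))
        return cfg


def _encode_covariates(df: pd.DataFrame, names) -> pd.DataFrame:
    """Numeric covariate design columns; positive/negative become 1/0."""
    out = {}
    for name in names:
        col = df[name]
        if col.dtype == object:
            out[name] = col.map(
                lambda v: 1.0 if str(v).lower() == "positive" else 0.0
            ).astype(float)
        else:
            out[name] = pd.to_numeric(col, errors="coerce").astype(float)
    enc = pd.DataFrame(out, index=df.index)
    return enc


def _response_arrays(
    matrix: GenotypeMatrix, clinical: ClinicalTable
) -> tuple[pd.DataFrame, np.ndarray]:
    """(clinical rows with a defined response, 0/1 responder vector)."""
    sub = clinical.neoadjuvant_with_response()
    y = (sub["response"] == "responder").to_numpy().astype(int)
    return sub, y


@dataclass
class TestingPhaseResult:
    panel: pd.DataFrame
    associations: pd.DataFrame
    filter_report: qc.FilterReport
    priority_calls: list
    funnel: dict[str, int]
    flipped_variants: list[str]


def run_testing_phase(
    genotypes: GenotypeMatrix,
    clinical: ClinicalTable,
    evidence: pd.DataFrame | None,
    cfg: RunConfig,
) -> TestingPhaseResult:
    """Full testing-phase analysis on in-memory inputs."""
    funnel: dict[str, int] = {"input_variants": genotypes.n_variants}
    oriented, flipped = variant_io.orient_to_common(genotypes)
    filtered, report = qc.apply_filters(oriented, cfg.thresholds)
    funnel["qc_pass"] = filtered.n_variants
    logger.info("QC: %d/%d variants pass (%s)", filtered.n_variants,
                genotypes.n_variants, report.totals)

    resp_clin, y_resp = _response_arrays(filtered, clinical)
    resp_sample_idx = [filtered.sample_ids.index(s) for s in resp_clin["sample_id"]]

    surv_clin = clinical.with_followup()
    surv_sample_idx = [filtered.sample_ids.index(s) for s in surv_clin["sample_id"]]
    t_raw = surv_clin["dfs_months"].to_numpy(dtype=float)
    e_raw = surv_clin["dfs_event"].to_numpy(dtype=bool)
    t_all, e_all = assoc.truncate_dfs(t_raw, e_raw, cfg.dfs_horizon)
    arm_strata = surv_clin["arm"].to_numpy()

    rows = []
    for vi, vid in enumerate(filtered.variant_ids):
        calls = filtered.calls[vi]
        n0, n1, n2, _ = qc._counts_from_row(calls)
        grouping = qc.collapse_rare(n0, n1, n2, cfg.thresholds.min_genotype_count)

        # response endpoint
        labels = grouping.labels(calls[resp_sample_idx])
        pr = assoc.perm_adjust(
            "response", y_resp, labels,
            n_permutations=cfg.response_permutations,
            seed=np.random.default_rng([cfg.seed, 1, vi]),
        )
        # survival endpoint, permuted within therapy arm
        s_labels = grouping.labels(calls[surv_sample_idx])
        ps = assoc.perm_adjust(
            "dfs", (t_all, e_all), s_labels,
            n_permutations=cfg.survival_permutations,
            strata=arm_strata,
            seed=np.random.default_rng([cfg.seed, 2, vi]),
        )

        sig_resp = pr.adjusted_p < cfg.alpha
        sig_dfs = ps.adjusted_p < cfg.alpha

        # gene-dosage gate, evaluated only where significance was claimed
        verdict_resp = verdict_dfs = dosage_gate.NOT_EVALUABLE
        if sig_resp and grouping.kind == qc.THREE_GROUP:
            table = assoc.contingency_from_labels(labels, y_resp)
            if table.shape == (3, 2) and (table.sum(axis=1) > 0).all():
                # column order (responder, non-responder)
                verdict_resp = dosage_gate.dosage_check_response(table[:, ::-1], vid).verdict
        if sig_dfs and grouping.kind == qc.THREE_GROUP:
            keep = s_labels >= 0
            curves = assoc.km_by_group(t_all[keep], e_all[keep], s_labels[keep])
            verdict_dfs = dosage_gate.dosage_check_survival(curves, vid, cfg.dfs_horizon).verdict
        if verdict_resp == dosage_gate.INCONSISTENT:
            sig_resp = False
        if verdict_dfs == dosage_gate.INCONSISTENT:
            sig_dfs = False

        endpoint = {
            (True, True): "both",
            (True, False): "response",
            (False, True): "dfs",
            (False, False): "none",
        }[(sig_resp, sig_dfs)]
        rows.append(
            {
                "variant_id": vid,
                "grouping": grouping.kind,
                "n0": n0, "n1": n1, "n2": n2,
                "response_raw_p": pr.raw_p,
                "response_adjusted_p": pr.adjusted_p,
                "dfs_raw_p": ps.raw_p,
                "dfs_adjusted_p": ps.adjusted_p,
                "dosage_response": verdict_resp,
                "dosage_dfs": verdict_dfs,
                "significant_endpoint": endpoint,
            }
        )
    associations = pd.DataFrame(rows)
    funnel["significant_response"] = int((associations["response_adjusted_p"] < cfg.alpha).sum())
    funnel["significant_dfs"] = int((associations["dfs_adjusted_p"] < cfg.alpha).sum())
    funnel["dosage_excluded"] = int(
        (associations[["dosage_response", "dosage_dfs"]] == dosage_gate.INCONSISTENT)
        .any(axis=1)
        .sum()
    )
    funnel["significant_after_gate"] = int((associations["significant_endpoint"] != "none").sum())
    logger.info("association: %d response-significant, %d DFS-significant, %d dosage-excluded",
                funnel["significant_response"], funnel["significant_dfs"],
                funnel["dosage_excluded"])

    # evidence integration
    calls_out = []
    ev_by_id = {}
    if evidence is not None and len(evidence):
        ev_by_id = {str(r["variant_id"]): r for _, r in evidence.iterrows()}
    for row in associations.itertuples():
        if row.significant_endpoint == "none":
            continue
        ev_row = ev_by_id.get(row.variant_id)
        if ev_row is not None:
            record = prioritize.EvidenceRecord.from_row(ev_row)
        else:
            record = prioritize.EvidenceRecord(variant_id=row.variant_id)
        calls_out.append(prioritize.call_priority(record, row.significant_endpoint))
    funnel["ranked"] = sum(1 for c in calls_out if c.level != "unranked")
    if calls_out and funnel["ranked"] == 0:
        logger.warning("no significant variant received a priority level; panel is empty")

    best_adj = {
        r.variant_id: float(np.nanmin([r.response_adjusted_p, r.dfs_adjusted_p]))
        for r in associations.itertuples()
    }
    panel = prioritize.build_panel(calls_out, best_adj, cfg.max_panel_size)
    funnel["panel"] = len(panel)
    logger.info("panel: %d variants (max %d)", len(panel), cfg.max_panel_size)
    return TestingPhaseResult(panel, associations, report, calls_out, funnel, flipped)


@dataclass
class ValidationPhaseResult:
    per_variant: pd.DataFrame
    subtype_tests: pd.DataFrame
    missing_variants: list[str]
    funnel: dict[str, int]


def run_validation_phase(
    genotypes: GenotypeMatrix,
    clinical: ClinicalTable,
    panel_variant_ids: list[str],
    cfg: RunConfig,
) -> ValidationPhaseResult:
    """Re-test panel variants in the validation cohort.

    Response: chi-square with permutation adjustment plus logistic regression
    adjusted for the configured response covariates.  Survival: log-rank on
    cytotoxic-therapy patients (permutations stratified by arm) plus Cox
    regression adjusted for the configured survival covariates, and a
    per-molecular-subtype log-rank table.  ``validated`` marks variants
    significant here (panel membership already encodes testing-phase
    significance) that also pass the dosage gate.
    """
    if not panel_variant_ids:
        raise ValueError("empty panel")
    present = [v for v in panel_variant_ids if v in genotypes.variant_ids]
    missing = [v for v in panel_variant_ids if v not in genotypes.variant_ids]
    if missing:
        logger.warning("panel variants absent from validation genotypes: %s", missing)
    matrix, _ = variant_io.orient_to_common(genotypes.subset_variants(present))

    resp_clin, y_resp = _response_arrays(matrix, clinical)
    resp_idx = [matrix.sample_ids.index(s) for s in resp_clin["sample_id"]]
    resp_covs = _encode_covariates(resp_clin, cfg.response_covariates)

    surv_clin = clinical.with_followup()
    cyto = surv_clin[surv_clin["arm"].isin(CYTOTOXIC_ARMS)]
    cyto_idx = [matrix.sample_ids.index(s) for s in cyto["sample_id"]]
    t_cyto, e_cyto = assoc.truncate_dfs(
        cyto["dfs_months"].to_numpy(dtype=float),
        cyto["dfs_event"].to_numpy(dtype=bool),
        cfg.dfs_horizon,
    )
    cyto_arm = cyto["arm"].to_numpy()
    cyto_covs = _encode_covariates(cyto, cfg.survival_covariates)
    subtypes = cyto["subtype"].to_numpy()

    horm = surv_clin[surv_clin["arm"] == "hormonal_only"]
    horm_idx = [matrix.sample_ids.index(s) for s in horm["sample_id"]]
    t_horm, e_horm = assoc.truncate_dfs(
        horm["dfs_months"].to_numpy(dtype=float),
        horm["dfs_event"].to_numpy(dtype=bool),
        cfg.dfs_horizon,
    )

    rows = []
    subtype_rows = []
    for vi, vid in enumerate(matrix.variant_ids):
        calls = matrix.calls[vi]
        n0, n1, n2, _ = qc._counts_from_row(calls)
        grouping = qc.collapse_rare(n0, n1, n2, cfg.thresholds.min_genotype_count)

        labels = grouping.labels(calls[resp_idx])
        pr = assoc.perm_adjust(
            "response", y_resp, labels,
            n_permutations=cfg.response_permutations,
            seed=np.random.default_rng([cfg.seed, 3, vi]),
        )
        keep = labels >= 0
        logit_fit = assoc.logistic_fit(
            y_resp[keep], labels[keep].astype(float), resp_covs.iloc[keep]
        )

        s_labels = grouping.labels(calls[cyto_idx])
        ps = assoc.perm_adjust(
            "dfs", (t_cyto, e_cyto), s_labels,
            n_permutations=cfg.survival_permutations,
            strata=cyto_arm,
            seed=np.random.default_rng([cfg.seed, 4, vi]),
        )
        skeep = s_labels >= 0
        cox = assoc.cox_fit(
            t_cyto[skeep], e_cyto[skeep], s_labels[skeep].astype(float),
            cyto_covs.iloc[skeep],
        )

        # hormonal-only therapy subset, raw log-rank only
        horm_p = np.nan
        if horm_idx:
            h_labels = grouping.labels(calls[horm_idx])
            hkeep = h_labels >= 0
            h_groups = [
                (t_horm[hkeep & (h_labels == g)], e_horm[hkeep & (h_labels == g)])
                for g in sorted(set(h_labels[hkeep].tolist()))
            ]
            h_groups = [g for g in h_groups if g[0].size > 0]
            if len(h_groups) >= 2:
                horm_p = assoc.logrank(h_groups).p_value

        verdict = dosage_gate.NOT_EVALUABLE
        if grouping.kind == qc.THREE_GROUP:
            curves = assoc.km_by_group(t_cyto[skeep], e_cyto[skeep], s_labels[skeep])
            verdict = dosage_gate.dosage_check_survival(curves, vid, cfg.dfs_horizon).verdict

        for st in pd.unique(subtypes):
            if not isinstance(st, str):
                continue
            m = skeep & (subtypes == st)
            if m.sum() < 2 or len(set(s_labels[m])) < 2:
                continue
            groups = [
                (t_cyto[m & (s_labels == g)], e_cyto[m & (s_labels == g)])
                for g in sorted(set(s_labels[m].tolist()))
            ]
            lr = assoc.logrank(groups)
            subtype_rows.append(
                {"variant_id": vid, "subtype": st, "n": int(m.sum()),
                 "logrank_p": lr.p_value, "flagged": lr.flagged}
            )

        sig_resp = pr.adjusted_p < cfg.alpha
        sig_dfs = ps.adjusted_p < cfg.alpha
        validated = (sig_resp or sig_dfs) and verdict != dosage_gate.INCONSISTENT
        rows.append(
            {
                "variant_id": vid,
                "grouping": grouping.kind,
                "n0": n0, "n1": n1, "n2": n2,
                "response_raw_p": pr.raw_p,
                "response_adjusted_p": pr.adjusted_p,
                "logistic_or": logit_fit.ratio,
                "logistic_lrt_p": logit_fit.lrt_p,
                "logistic_flagged": logit_fit.flagged,
                "dfs_raw_p": ps.raw_p,
                "dfs_adjusted_p": ps.adjusted_p,
                "dfs_hormonal_p": horm_p,
                "cox_hr": cox.ratio,
                "cox_ci_low": cox.ci_low,
                "cox_ci_high": cox.ci_high,
                "cox_lrt_p": cox.lrt_p,
                "cox_flagged": cox.flagged,
                "dosage_dfs": verdict,
                "validated": validated,
            }
        )
    per_variant = pd.DataFrame(rows)
    funnel = {
        "panel_variants": len(panel_variant_ids),
        "genotyped": len(present),
        "validated": int(per_variant["validated"].sum()) if len(per_variant) else 0,
    }
    logger.info("validation: %s", funnel)
    return ValidationPhaseResult(per_variant, pd.DataFrame(subtype_rows), missing, funnel)


def compare_maf_sets(
    set_a_counts: dict[str, tuple[int, int, int]],
    set_b_counts: dict[str, tuple[int, int, int]],
) -> pd.DataFrame:
    """Per-variant MAF in two cohorts plus absolute drift, on shared ids."""
    shared = sorted(set(set_a_counts) & set(set_b_counts))
    rows = []
    for vid in shared:
        maf_a = qc.compute_maf(*set_a_counts[vid])
        maf_b = qc.compute_maf(*set_b_counts[vid])
        rows.append(
            {"variant_id": vid, "maf_a": maf_a, "maf_b": maf_b,
             "abs_diff": abs(maf_a - maf_b)}
        )
    return pd.DataFrame(rows, columns=["variant_id", "maf_a", "maf_b", "abs_diff"])


# ---------------------------------------------------------------------------
# file-level runner
# ---------------------------------------------------------------------------

def run(cfg: RunConfig) -> None:
    """Load the configured inputs, execute the phase, write TSV reports."""
    import os

    os.makedirs(cfg.out_dir, exist_ok=True)
    genotypes = variant_io.read_genotypes(cfg.genotypes_path, cfg.genotypes_format)
    clinical = variant_io.read_clinical(cfg.clinical_path)
    if cfg.phase == "testing":
        evidence = variant_io.read_evidence(cfg.evidence_path) if cfg.evidence_path else None
        result = run_testing_phase(genotypes, clinical, evidence, cfg)
        variant_io.write_report(result.associations, f"{cfg.out_dir}/associations.tsv", cfg.seed)
        variant_io.write_report(result.filter_report.per_variant, f"{cfg.out_dir}/qc.tsv", cfg.seed)
        variant_io.write_report(result.panel, f"{cfg.out_dir}/panel.tsv", cfg.seed)
    else:
        panel = variant_io.read_report(cfg.panel_path)
        result = run_validation_phase(
            genotypes, clinical, panel["variant_id"].astype(str).tolist(), cfg
        )
        variant_io.write_report(result.per_variant, f"{cfg.out_dir}/validation.tsv", cfg.seed)
        variant_io.write_report(result.subtype_tests, f"{cfg.out_dir}/subtype_tests.tsv", cfg.seed)
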