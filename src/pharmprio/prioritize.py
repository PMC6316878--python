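"""Evidence integration and panel selection.

Combines three ingredients per variant:

1. statistical significance (permutation-adjusted p below alpha on either
   endpoint),
2. database evidence (PharmGKB association status, ClinVar record class),
3. an in-silico deleteriousness consensus over class-appropriate tools,

into a four-level priority call (highest / high / medium / low) via a
decision matrix, and emits a deterministic ranked validation panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

VARIANT_CLASSES = (
    "missense",
    "synonymous",
    "splice-site",
    "utr",
    "intronic/intergenic",
    "indel",
)

DELETERIOUS = "deleterious"
NEUTRAL = "neutral"
UNKNOWN = "unknown"

LEVELS = ("highest", "high", "medium", "low", "unranked")
_LEVEL_RANK = {lev: i for i, lev in enumerate(LEVELS)}

CADD_CUTOFF = 19.0
SIFT_CUTOFF = 0.05
PINES_CUTOFF = 0.05
IW_CUTOFF = 0.01
DBSCSNV_CUTOFF = 0.6


def _missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    if isinstance(value, str) and value.strip() in ("", "."):
        return True
    return False


@dataclass
class EvidenceRecord:
    """Per-variant database flags and in-silico tool outputs.

    Tool fields use ``None`` (or NaN / ".") for "no prediction available".
    """

    variant_id: str
    variant_class: str = "intronic/intergenic"
    pharmgkb: str = "no-data"        # associated | no-data
    clinvar: str = "no-data"         # drug-response | cancer/neoplasm | other | no-data
    cancer_related: bool = False
    mutation_assessor: str | None = None   # H | M | L | N
    sift_score: float | None = None
    lrt_pred: str | None = None            # D | N | U
    provean_pred: str | None = None        # D | N
    cadd_phred: float | None = None
    dbscsnv_ada: float | None = None
    maxentscan_ref: float | None = None
    maxentscan_alt: float | None = None
    regulome_category: str | None = None
    pines_p: float | None = None
    iw_score: float | None = None
    mirna_site: bool | None = None

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"{self.variant_id}: unknown variant class {self.variant_class!r}")
        if self.pharmgkb not in ("associated", "no-data"):
            raise ValueError(f"{self.variant_id}: bad pharmgkb status {self.pharmgkb!r}")
        if self.clinvar not in ("drug-response", "cancer/neoplasm", "other", "no-data"):
            raise ValueError(f"{self.variant_id}: bad clinvar status {self.clinvar!r}")
        for name in ("sift_score", "cadd_phred", "dbscsnv_ada", "pines_p"):
            v = getattr(self, name)
            if _missing(v):
                setattr(self, name, None)

    @classmethod
    def from_row(cls, row: Mapping) -> "EvidenceRecord":
        def get(col):
            v = row.get(col) if hasattr(row, "get") else row[col]
            return None if _missing(v) else v

        def fnum(col):
            v = get(col)
            return None if v is None else float(v)

        def fbool(col):
            v = get(col)
            if v is None:
                return None
            if isinstance(v, str):
                return v.strip().lower() in ("1", "true", "yes")
            return bool(v)

        return cls(
            variant_id=str(row["variant_id"]),
            variant_class=get("variant_class") or "intronic/intergenic",
            pharmgkb=get("pharmgkb") or "no-data",
            clinvar=get("clinvar") or "no-data",
            cancer_related=bool(fbool("cancer_related")),
            mutation_assessor=get("mutation_assessor"),
            sift_score=fnum("sift_score"),
            lrt_pred=get("lrt_pred"),
            provean_pred=get("provean_pred"),
            cadd_phred=fnum("cadd_phred"),
            dbscsnv_ada=fnum("dbscsnv_ada"),
            maxentscan_ref=fnum("maxentscan_ref"),
            maxentscan_alt=fnum("maxentscan_alt"),
            regulome_category=None if _missing(row.get("regulome_category")) else str(row.get("regulome_category")),
            pines_p=fnum("pines_p"),
            iw_score=fnum("iw_score"),
            mirna_site=fbool("mirna_site"),
        )


def insilico_consensus(e: EvidenceRecord) -> str:
    """Class-appropriate in-silico deleteriousness call.

    Missense: strict four-tool consensus (Mutation Assessor H/M, SIFT <= 0.05,
    LRT D, PROVEAN D); any missing tool makes the call *unknown*.
    Splice-site: alternative splice score below the reference score marks
    putative splice disruption.
    Synonymous and non-coding classes: any of RegulomeDB category 1,
    PINES p <= 0.05, IW score < 0.01, or a conserved miRNA site.
    A CADD PHRED score >= 19 upgrades a neutral or unknown call of any class
    to deleterious.
    """
    cls = e.variant_class
    if cls == "missense":
        tools = (e.mutation_assessor, e.sift_score, e.lrt_pred, e.provean_pred)
        if any(_missing(t) for t in tools):
            call = UNKNOWN
        elif (
            e.mutation_assessor in ("H", "M")
            and e.sift_score <= SIFT_CUTOFF
            and e.lrt_pred == "D"
            and e.provean_pred == "D"
        ):
            call = DELETERIOUS
        else:
            call = NEUTRAL
    elif cls == "splice-site":
        if e.maxentscan_ref is not None and e.maxentscan_alt is not None:
            call = DELETERIOUS if e.maxentscan_alt < e.maxentscan_ref else NEUTRAL
        elif e.dbscsnv_ada is not None:
            call = DELETERIOUS if e.dbscsnv_ada >= DBSCSNV_CUTOFF else NEUTRAL
        else:
            call = UNKNOWN
    else:  # synonymous, utr, intronic/intergenic, indel
        signals = [
            e.regulome_category == "1",
            e.pines_p is not None and e.pines_p <= PINES_CUTOFF,
            e.iw_score is not None and e.iw_score < IW_CUTOFF,
            bool(e.mirna_site),
        ]
        present = [
            e.regulome_category is not None,
            e.pines_p is not None,
            e.iw_score is not None,
            e.mirna_site is not None,
        ]
        if any(signals):
            call = DELETERIOUS
        elif not any(present):
            call = UNKNOWN
        else:
            call = NEUTRAL
    if call != DELETERIOUS and e.cadd_phred is not None and e.cadd_phred >= CADD_CUTOFF:
        call = DELETERIOUS
    return call


@dataclass
class PriorityCall:
    variant_id: str
    significant_endpoint: str  # response | dfs | both | none
    insilico_call: str
    level: str
    rationale: list[str] = field(default_factory=list)


def assign_priority(
    significant: bool,
    pharmgkb: str,
    clinvar: str,
    insilico_call: str,
    cancer_related: bool,
) -> tuple[str, list[str]]:
    """Priority level from the decision matrix; returns (level, rationale).

    Columns are evaluated left to right (highest -> low), first match wins.
    A ClinVar record outside drug-response / cancer-neoplasm counts as
    no-data.  An *unknown* in-silico call counts as neutral where a column
    accepts neutral, and fails columns requiring deleterious.  Significance
    is mandatory in every column.
    """
    if clinvar == "other":
        clinvar = "no-data"
    if not significant:
        return "unranked", ["not significant on any endpoint"]
    clinvar_hit = clinvar in ("drug-response", "cancer/neoplasm")
    deleterious = insilico_call == DELETERIOUS
    neutral_like = insilico_call in (NEUTRAL, UNKNOWN)
    if pharmgkb == "associated" and clinvar_hit and deleterious and not cancer_related:
        return "highest", ["PharmGKB associated", f"ClinVar {clinvar}", "in-silico deleterious"]
    if pharmgkb == "associated" and clinvar == "no-data" and (deleterious or neutral_like) and not cancer_related:
        return "high", ["PharmGKB associated", "no ClinVar record", f"in-silico {insilico_call}"]
    if pharmgkb == "no-data" and clinvar_hit and deleterious and not cancer_related:
        return "medium", [f"ClinVar {clinvar}", "in-silico deleterious"]
    if pharmgkb == "no-data" and clinvar == "no-data" and neutral_like and cancer_related:
        return "low", ["cancer-related functionality only", f"in-silico {insilico_call}"]
    return "unranked", ["significant but no priority column matched"]


def call_priority(
    e: EvidenceRecord, significant_endpoint: str
) -> PriorityCall:
    """Full priority call for one variant given its evidence record."""
    call = insilico_consensus(e)
    level, rationale = assign_priority(
        significant=significant_endpoint != "none",
        pharmgkb=e.pharmgkb,
        clinvar=e.clinvar,
        insilico_call=call,
        cancer_related=e.cancer_related,
    )
    rationale = [f"significant: {significant_endpoint}"] + rationale
    return PriorityCall(e.variant_id, significant_endpoint, call, level, rationale)


def build_panel(
    priority_calls: list[PriorityCall],
    adjusted_p: Mapping[str, float],
    max_size: int | None = None,
) -> pd.DataFrame:
    """Rank prioritized variants into the validation panel.

    Ordering: priority level, then smaller adjusted p, then variant id (a
    total, deterministic order).  Unranked variants never enter the panel.
    """
    rows = []
    for call in priority_calls:
        if call.level == "unranked":
            continue
        if not call.rationale:
            raise ValueError(f"{call.variant_id}: empty rationale on a ranked call")
        rows.append(
            {
                "variant_id": call.variant_id,
                "level": call.level,
                "significant_endpoint": call.significant_endpoint,
                "insilico_call": call.insilico_call,
                "adjusted_p": float(adjusted_p.get(call.variant_id, np.nan)),
                "rationale": "; ".join(call.rationale),
            }
        )
    panel = pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "level",
            "significant_endpoint",
            "insilico_call",
            "adjusted_p",
            "rationale",
        ],
    )
    if panel.empty:
        return panel
    panel["_rank"] = panel["level"].map(_LEVEL_RANK)
    panel = panel.sort_values(
        ["_rank", "adjusted_p", "variant_id"], kind="mergesort", na_position="last"
    ).drop(columns="_rank")
    if max_size is not None:
        panel = panel.head(max_size)
    return panel.reset_index(drop=True)
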