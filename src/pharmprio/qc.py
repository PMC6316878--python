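"""Per-variant quality control.

Implements the filter cascade applied before any association testing:
minor allele frequency > 0.05, exact Hardy-Weinberg p > 0.01, and missing
data in fewer than 50% of samples — plus genotype-group collapsing for
sparse homozygote classes and the cross-platform non-reference discordance
rate used to check genotyping concordance.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .variant_io import MISSING, GenotypeMatrix

VERDICT_PASS = "pass"
VERDICT_FAIL_MAF = "fail_maf"
VERDICT_FAIL_HWE = "fail_hwe"
VERDICT_FAIL_MISSING = "fail_missing"
VERDICTS = (VERDICT_PASS, VERDICT_FAIL_MAF, VERDICT_FAIL_HWE, VERDICT_FAIL_MISSING)


@dataclass(frozen=True)
class QcThresholds:
    """Filter cut-offs; defaults follow the analysis protocol."""

    hwe_alpha: float = 0.01
    maf_min: float = 0.05
    max_missing_fraction: float = 0.5
    min_genotype_count: int = 5

    def __post_init__(self) -> None:
        for name in ("hwe_alpha", "maf_min", "max_missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.min_genotype_count < 1:
            raise ValueError("min_genotype_count must be >= 1")


@dataclass
class FilterReport:
    """Per-variant QC metrics plus cohort totals per verdict."""

    per_variant: pd.DataFrame  # variant_id, maf, hwe_p, missing_fraction, verdict
    totals: dict[str, int]


def genotype_counts(matrix: GenotypeMatrix, variant_id: str) -> tuple[int, int, int, int]:
    """(n common hom, n het, n rare hom, n missing) for one variant."""
    row = matrix.row(variant_id)
    return _counts_from_row(row)


def _counts_from_row(row: np.ndarray) -> tuple[int, int, int, int]:
    n0 = int(np.count_nonzero(row == 0))
    n1 = int(np.count_nonzero(row == 1))
    n2 = int(np.count_nonzero(row == 2))
    nm = int(np.count_nonzero(row == MISSING))
    return n0, n1, n2, nm


class UndefinedMafError(ValueError):
    """No informative (non-missing) genotypes."""


def compute_maf(n0: int, n1: int, n2: int) -> float:
    """Minor allele frequency from genotype counts.

    q = (n1 + 2*n2) / (2*(n0 + n1 + n2)); MAF = min(q, 1 - q).
    """
    total = n0 + n1 + n2
    if total <= 0:
        raise UndefinedMafError("no informative genotypes")
    q = (n1 + 2 * n2) / (2.0 * total)
    return min(q, 1.0 - q)


@lru_cache(maxsize=100_000)
def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Two-sided exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability is less than or
    equal to that of the observed configuration.  Monomorphic sites return 1.
    Symmetric in (n0, n2).
    """
    if min(n0, n1, n2) < 0:
        raise ValueError("negative genotype counts")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("no informative genotypes")
    n_alt = n1 + 2 * n2
    rare = min(n_alt, 2 * n - n_alt)
    if rare == 0:
        return 1.0
    # Possible het counts share the parity of the rare-allele count.
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    valid = hom_common >= 0
    hets, hom_rare, hom_common = hets[valid], hom_rare[valid], hom_common[valid]
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_common + 1)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
    )
    logp -= logsumexp(logp)  # normalize; shared combinatorial terms cancel
    probs = np.exp(logp)
    p_obs = probs[hets == n1][0]
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def apply_filters(
    matrix: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the MAF / HWE / missingness cascade on every variant.

    A variant passes iff MAF > maf_min AND HWE p > hwe_alpha AND missing
    fraction < max_missing_fraction.  The recorded verdict is the first
    failing rule in the order maf -> hwe -> missing (report bookkeeping only;
    the pass/fail set does not depend on that order).  The missing-fraction
    denominator is the full cohort sample count.  Variants with no
    informative calls are recorded as ``fail_missing``.
    """
    thresholds = thresholds or QcThresholds()
    n_samples = matrix.n_samples
    rows = []
    for vid, row in zip(matrix.variant_ids, matrix.calls):
        n0, n1, n2, nm = _counts_from_row(row)
        missing_fraction = nm / n_samples if n_samples else 1.0
        if n0 + n1 + n2 == 0:
            rows.append((vid, np.nan, np.nan, missing_fraction, VERDICT_FAIL_MISSING))
            continue
        maf = compute_maf(n0, n1, n2)
        hwe_p = hwe_exact_test(n0, n1, n2)
        if not maf > thresholds.maf_min:
            verdict = VERDICT_FAIL_MAF
        elif not hwe_p > thresholds.hwe_alpha:
            verdict = VERDICT_FAIL_HWE
        elif not missing_fraction < thresholds.max_missing_fraction:
            verdict = VERDICT_FAIL_MISSING
        else:
            verdict = VERDICT_PASS
        rows.append((vid, maf, hwe_p, missing_fraction, verdict))
    per_variant = pd.DataFrame(
        rows, columns=["variant_id", "maf", "hwe_p", "missing_fraction", "verdict"]
    )
    totals = {v: int((per_variant["verdict"] == v).sum()) for v in VERDICTS}
    passing = per_variant.loc[per_variant["verdict"] == VERDICT_PASS, "variant_id"].tolist()
    return matrix.subset_variants(passing), FilterReport(per_variant, totals)


# ---------------------------------------------------------------------------
# genotype-group collapsing
# ---------------------------------------------------------------------------

THREE_GROUP = "three_group"
RARE_ALLELE = "rare_allele"     # rare hom merged into het: {0} vs {1,2}
COMMON_ALLELE = "common_allele"  # common hom merged into het: {0,1} vs {2}


@dataclass(frozen=True)
class Grouping:
    """How genotype codes map to comparison groups for one variant."""

    kind: str
    group_of_code: tuple[int, int, int]  # comparison group per genotype code 0/1/2

    @property
    def n_groups(self) -> int:
        return len(set(self.group_of_code))

    def labels(self, calls: np.ndarray) -> np.ndarray:
        """Group label per sample; missing calls map to -1."""
        calls = np.asarray(calls)
        out = np.full(calls.shape, -1, dtype=int)
        for code, grp in enumerate(self.group_of_code):
            out[calls == code] = grp
        return out

    def group_names(self) -> list[str]:
        if self.kind == THREE_GROUP:
            return ["common_hom", "het", "rare_hom"]
        if self.kind == RARE_ALLELE:
            return ["common_hom", "rare_allele"]
        return ["common_allele", "rare_hom"]


def collapse_rare(n0: int, n1: int, n2: int, min_count: int = 5) -> Grouping:
    """Merge a homozygote class observed in fewer than ``min_count`` samples
    into the heterozygote class, yielding a two-group comparison.

    The boundary is strict: a class with exactly ``min_count`` members keeps
    three groups.
    """
    if min(n0, n1, n2) < 0:
        raise ValueError("negative genotype counts")
    if n2 < min_count:
        return Grouping(RARE_ALLELE, (0, 1, 1))
    if n0 < min_count:
        return Grouping(COMMON_ALLELE, (0, 0, 1))
    return Grouping(THREE_GROUP, (0, 1, 2))


# ---------------------------------------------------------------------------
# cross-platform concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscordanceResult:
    rate_percent: float  # NaN when undefined
    n_discordant: int
    n_nonref_pairs: int

    @property
    def defined(self) -> bool:
        return self.n_nonref_pairs > 0


def nonref_discordance(calls_a: np.ndarray, calls_b: np.ndarray) -> DiscordanceResult:
    """Non-reference discordance between two aligned call vectors, in percent.

    Pairs with a missing call on either side are dropped.  The denominator is
    the number of pairs where at least one platform calls a non-reference
    genotype; the rate is the percentage of those pairs that disagree.
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape:
        raise ValueError("call vectors are not aligned")
    keep = (a != MISSING) & (b != MISSING)
    a, b = a[keep], b[keep]
    nonref = (a != 0) | (b != 0)
    n_pairs = int(nonref.sum())
    if n_pairs == 0:
        return DiscordanceResult(float("nan"), 0, 0)
    n_disc = int(((a != b) & nonref).sum())
    return DiscordanceResult(100.0 * n_disc / n_pairs, n_disc, n_pairs)
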