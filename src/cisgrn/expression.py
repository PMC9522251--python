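"""FACS-compartment expression profiling.

Per-gene proportional expression across the X1/X2/Xins compartments, the
information-content scalar summarising compartment specificity, and the
seven-way enrichment classification.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

COMPARTMENTS = ("X1", "X2", "Xins")

#: Proportions below this floor are clamped before the IC formula is evaluated.
IC_FLOOR = 0.01


class UnexpressedGeneError(ValueError):
    """Gene with zero TPM in every compartment: proportions are undefined."""


class EnrichmentCategory(str, enum.Enum):
    X1 = "X1"
    X2 = "X2"
    XINS = "Xins"
    X1_X2 = "X1_X2"
    X1_XINS = "X1_Xins"
    X2_XINS = "X2_Xins"
    UBIQUITOUS = "ubiquitous"


@dataclass(frozen=True)
class CompartmentExpression:
    """Mean TPM of one gene in each FACS compartment."""

    gene_id: str
    tpm_x1: float
    tpm_x2: float
    tpm_xins: float

    def __post_init__(self) -> None:
        for v in (self.tpm_x1, self.tpm_x2, self.tpm_xins):
            if v < 0:
                raise ValueError(f"negative TPM for {self.gene_id}")

    @property
    def total(self) -> float:
        return self.tpm_x1 + self.tpm_x2 + self.tpm_xins


@dataclass(frozen=True)
class ProportionProfile:
    """Proportional expression (p1, p2, p3) = (X1%, X2%, Xins%)."""

    gene_id: str
    p1: float
    p2: float
    p3: float
    ic: Optional[float] = None
    category: Optional[EnrichmentCategory] = None

    def __post_init__(self) -> None:
        s = self.p1 + self.p2 + self.p3
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"proportions for {self.gene_id} sum to {s}, not 1")
        for p in (self.p1, self.p2, self.p3):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion {p} outside [0,1] for {self.gene_id}")

    @property
    def proportions(self) -> Tuple[float, float, float]:
        return (self.p1, self.p2, self.p3)


def summarize_compartments(
    per_sample_tpm: pd.DataFrame,
    sample_to_compartment: Mapping[str, str],
) -> List[CompartmentExpression]:
    """Mean TPM per FACS compartment for every gene.

    Parameters
    ----------
    per_sample_tpm
        Genes x samples TPM table (index = gene_id).
    sample_to_compartment
        Maps every sample column to one of ``X1``, ``X2``, ``Xins``.
    """
    for sample in per_sample_tpm.columns:
        if sample not in sample_to_compartment:
            raise ValueError(f"sample {sample!r} has no compartment label")
    for sample, comp in sample_to_compartment.items():
        if comp not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {comp!r} for sample {sample!r}")
    groups: Dict[str, list] = {c: [] for c in COMPARTMENTS}
    for sample in per_sample_tpm.columns:
        groups[sample_to_compartment[sample]].append(sample)
    for comp, samples in groups.items():
        if not samples:
            raise ValueError(f"compartment {comp} has no samples")
    means = {c: per_sample_tpm[groups[c]].mean(axis=1) for c in COMPARTMENTS}
    return [
        CompartmentExpression(
            gene_id=str(gene),
            tpm_x1=float(means["X1"][gene]),
            tpm_x2=float(means["X2"][gene]),
            tpm_xins=float(means["Xins"][gene]),
        )
        for gene in per_sample_tpm.index
    ]


def proportional_expression(e: CompartmentExpression) -> ProportionProfile:
    """Compartment TPM divided by the summed TPM across compartments.

    Raises
    ------
    UnexpressedGeneError
        If the gene has zero TPM everywhere; such genes are excluded
        downstream rather than silently assigned (1/3, 1/3, 1/3).
    """
    total = e.total
    if total <= 0:
        raise UnexpressedGeneError(f"gene {e.gene_id} has zero TPM in all compartments")
    return ProportionProfile(
        gene_id=e.gene_id,
        p1=e.tpm_x1 / total,
        p2=e.tpm_x2 / total,
        p3=e.tpm_xins / total,
    )


def information_content(p1: float, p2: float, p3: float, *, base: str = "e") -> float:
    """Compartment-specificity scalar ``0.01*sum(p_i * log p_i)``.

    Each proportion is clamped to ``max(p, 0.01)`` before the formula is
    evaluated, so the result is finite everywhere; it is always <= 0 and
    closer to 0 for more compartment-specific genes.  The 0.01 prefactor
    is retained exactly as defined even though it is a pure scale factor.
    Natural log by default; ``base='2'`` or ``'10'`` are accepted since the
    log base only rescales.
    """
    log = {"e": math.log, "2": math.log2, "10": math.log10}[base]
    clamped = [max(p, IC_FLOOR) for p in (p1, p2, p3)]
    return 0.01 * sum(p * log(p) for p in clamped)


def classify_enrichment(
    p1: float, p2: float, p3: float, *, strict: bool = True
) -> EnrichmentCategory:
    """Assign the seven-way FACS enrichment category.

    Single-compartment rules (p_i > 0.5) are evaluated first, then pairwise
    rules (p_i + p_j > 0.75, with neither single rule firing), then
    ubiquitous.  ``strict=True`` uses strict ``>`` at both thresholds;
    ``strict=False`` uses ``>=``.
    """
    exceeds = (lambda v, t: v > t) if strict else (lambda v, t: v >= t)
    singles = {
        EnrichmentCategory.X1: exceeds(p1, 0.5),
        EnrichmentCategory.X2: exceeds(p2, 0.5),
        EnrichmentCategory.XINS: exceeds(p3, 0.5),
    }
    for cat in (EnrichmentCategory.X1, EnrichmentCategory.X2, EnrichmentCategory.XINS):
        if singles[cat]:
            return cat
    if exceeds(p1 + p2, 0.75):
        return EnrichmentCategory.X1_X2
    if exceeds(p1 + p3, 0.75):
        return EnrichmentCategory.X1_XINS
    if exceeds(p2 + p3, 0.75):
        return EnrichmentCategory.X2_XINS
    return EnrichmentCategory.UBIQUITOUS


def profile_genes(
    expressions: Sequence[CompartmentExpression], *, strict: bool = True
) -> Tuple[List[ProportionProfile], List[str]]:
    """Full per-gene profile (proportions, IC, category).

    Returns the profiles and the list of unexpressed gene ids that were
    excluded.
    """
    profiles: List[ProportionProfile] = []
    unexpressed: List[str] = []
    for e in expressions:
        try:
            p = proportional_expression(e)
        except UnexpressedGeneError:
            unexpressed.append(e.gene_id)
            continue
        profiles.append(ProportionProfile(
            gene_id=p.gene_id,
            p1=p.p1, p2=p.p2, p3=p.p3,
            ic=information_content(p.p1, p.p2, p.p3),
            category=classify_enrichment(p.p1, p.p2, p.p3, strict=strict),
        ))
    return profiles, unexpressed


def profiles_table(
    expressions: Sequence[CompartmentExpression], *, strict: bool = True
) -> pd.DataFrame:
    """Tabular export: gene_id, TPMs, proportions, IC, category."""
    profiles, _ = profile_genes(expressions, strict=strict)
    by_id = {e.gene_id: e for e in expressions}
    rows = []
    for p in profiles:
        e = by_id[p.gene_id]
        rows.append({
            "gene_id": p.gene_id,
            "tpm_x1": e.tpm_x1, "tpm_x2": e.tpm_x2, "tpm_xins": e.tpm_xins,
            "p1": p.p1, "p2": p.p2, "p3": p.p3,
            "ic": p.ic, "category": p.category.value,
        })
    return pd.DataFrame(rows)


def compare_groups(
    samples: Sequence[Sequence[float]], test: str
) -> Tuple[float, float]:
    """Two-sided group comparison.

    ``kruskal``: Kruskal-Wallis across >= 2 groups.  ``wilcoxon``: rank-sum
    between exactly 2 groups (normal approximation with tie correction for
    larger samples).  ``chi2_yates``: chi-square with Yates continuity
    correction on a 2x2 count table.
    """
    if test == "kruskal":
        if len(samples) < 2:
            raise ValueError("kruskal needs >= 2 groups")
        _check_nonempty(samples)
        res = stats.kruskal(*samples)
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon":
        if len(samples) != 2:
            raise ValueError("wilcoxon needs exactly 2 groups")
        _check_nonempty(samples)
        return wilcoxon_rank_sum(samples[0], samples[1])
    if test == "chi2_yates":
        return chi2_yates(np.asarray(samples, dtype=np.float64))
    raise ValueError(f"unknown test {test!r}")


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise (scipy's ``method='auto'``).
    """
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def chi2_yates(table: np.ndarray) -> Tuple[float, float]:
    """Chi-square test of a 2x2 table with Yates continuity correction."""
    table = np.asarray(table, dtype=np.float64)
    if table.shape != (2, 2):
        raise ValueError("chi2_yates needs a 2x2 count table")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    stat, p, _dof, expected = stats.chi2_contingency(table, correction=True)
    if np.any(expected < 1):
        warnings.warn("chi2_yates: expected cell count < 1; test unreliable",
                      stacklevel=2)
    return float(stat), float(p)


def _check_nonempty(samples: Sequence[Sequence[float]]) -> None:
    for i, s in enumerate(samples):
        if len(s) == 0:
            raise ValueError(f"group {i} is empty")
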