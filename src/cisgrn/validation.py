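"""Observed/expected regulatory-link validation against knockdown DE sets.

For a knocked-down TF, the observed count is the number of differentially
expressed TF genes that carry a footprint link from that TF in their
enhancer.  Under independence of (A) being differentially expressed,
(B) being linked to an enhancer, and (C) that enhancer containing the
knockdown TF's footprint, the expected count is

    P(A) * P(B) * P(C) * nge  =  (ndge/nge) * (ncis/nge) * (ncisTF/ncis) * nge
                               =  ndge * ncisTF / nge

All counts are over the TF gene universe.  Significance comes from a
permutation test that resamples the DE label set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from cisgrn.grn import RegulatoryLink

CLASSES = ("bound", "unbound")


@dataclass(frozen=True)
class KnockdownExperiment:
    """One RNAi knockdown with its set of differentially expressed TFs."""

    knockdown_tf: str
    detf_set: frozenset

    @classmethod
    def make(cls, knockdown_tf: str, detfs: Sequence[str]) -> "KnockdownExperiment":
        return cls(knockdown_tf=knockdown_tf, detf_set=frozenset(detfs))


@dataclass
class ClassResult:
    """Per footprint-class (bound/unbound) counts for one knockdown."""

    ncis_tf: int
    observed: int
    expected: float
    ratio: Optional[float]  # None when expected == 0
    p_perm: Optional[float] = None


@dataclass
class LinkEnrichmentResult:
    knockdown_tf: str
    nge: int
    ndge: int
    ncis: int
    by_class: Dict[str, ClassResult] = field(default_factory=dict)


def expected_links(nge: int, ndge: int, ncis: int, ncis_tf: int) -> float:
    """Expected DE-and-linked-and-footprinted count under independence.

    Evaluates the full product P(A)*P(B)*P(C)*nge and asserts it equals the
    algebraic simplification ndge*ncisTF/nge.
    """
    if nge <= 0:
        raise ValueError("nge must be positive")
    if not (0 <= ndge <= nge):
        raise ValueError("need 0 <= ndge <= nge")
    if not (0 <= ncis_tf <= ncis <= nge):
        raise ValueError("need 0 <= ncisTF <= ncis <= nge")
    if ncis == 0:
        if ncis_tf > 0:
            raise ValueError("ncisTF > 0 with ncis == 0")
        return 0.0
    full = (ndge / nge) * (ncis / nge) * (ncis_tf / ncis) * nge
    simplified = ndge * ncis_tf / nge
    assert math.isclose(full, simplified, rel_tol=1e-12, abs_tol=1e-12)
    return full


def _link_targets(
    links: Sequence[RegulatoryLink], tf_universe: Set[str]
) -> Tuple[Set[str], Dict[str, Dict[str, Set[str]]]]:
    """(all cis-linked TF targets, per-TF per-class target sets).

    Only links whose target is in the TF universe count; unknown targets
    are ignored, matching the all-counts-over-TFs convention.
    """
    cis_linked: Set[str] = set()
    per_tf: Dict[str, Dict[str, Set[str]]] = {}
    for link in links:
        if link.target_gene_id not in tf_universe:
            continue
        cis_linked.add(link.target_gene_id)
        cls = "bound" if link.bound else "unbound"
        per_tf.setdefault(link.tf_gene_id, {"bound": set(), "unbound": set()})
        per_tf[link.tf_gene_id][cls].add(link.target_gene_id)
    return cis_linked, per_tf


def observed_links(
    experiment: KnockdownExperiment,
    links: Sequence[RegulatoryLink],
    footprint_class: str,
    tf_universe: Set[str],
) -> int:
    """Distinct TF targets of the knockdown TF, of the given class, that are DE."""
    if footprint_class not in CLASSES:
        raise ValueError(f"unknown footprint class {footprint_class!r}")
    _, per_tf = _link_targets(links, tf_universe)
    targets = per_tf.get(experiment.knockdown_tf, {}).get(footprint_class, set())
    return len(targets & experiment.detf_set)


def oe_ratio(
    experiment: KnockdownExperiment,
    links: Sequence[RegulatoryLink],
    tf_universe: Set[str],
) -> LinkEnrichmentResult:
    """Per-class observed, expected, and observed/expected for one knockdown.

    The ratio is reported as missing (``None``) when the expected count is
    zero; coercing it to 0 or infinity would bias cohort means.
    """
    if experiment.knockdown_tf not in tf_universe:
        raise ValueError(f"knockdown TF {experiment.knockdown_tf!r} not in universe")
    detfs = experiment.detf_set & tf_universe
    nge = len(tf_universe)
    ndge = len(detfs)
    cis_linked, per_tf = _link_targets(links, tf_universe)
    ncis = len(cis_linked)
    result = LinkEnrichmentResult(
        knockdown_tf=experiment.knockdown_tf, nge=nge, ndge=ndge, ncis=ncis
    )
    targets_by_class = per_tf.get(experiment.knockdown_tf,
                                  {"bound": set(), "unbound": set()})
    for cls in CLASSES:
        targets = targets_by_class.get(cls, set())
        ncis_tf = len(targets)
        observed = len(targets & detfs)
        expected = expected_links(nge, ndge, ncis, ncis_tf)
        ratio = observed / expected if expected > 0 else None
        result.by_class[cls] = ClassResult(
            ncis_tf=ncis_tf, observed=observed, expected=expected, ratio=ratio
        )
    return result


def _resample_observed(
    n_targets: int, nge: int, ndge: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Observed counts under the DE-resampling null.

    Each permutation draws ndge TFs uniformly without replacement from the
    universe and counts how many fall in the (fixed) target set.  The draw
    is realised by ranking i.i.d. uniforms per permutation, which is an
    exact uniform subset sample.
    """
    if n_targets == 0 or ndge == 0:
        return np.zeros(n_perm, dtype=np.int64)
    keys = rng.random((n_perm, nge))
    chosen = np.argpartition(keys, ndge - 1, axis=1)[:, :ndge]
    is_target = np.zeros(nge, dtype=bool)
    is_target[:n_targets] = True  # target identity is exchangeable under the null
    return is_target[chosen].sum(axis=1)


def permutation_p(
    experiment: KnockdownExperiment,
    links: Sequence[RegulatoryLink],
    tf_universe: Set[str],
    n_perm: int = 1000,
    seed: int = 0,
    *,
    null: str = "de",
) -> Dict[str, float]:
    """Permutation p-value per footprint class.

    The default ``null='de'`` resamples the DE label set: ndge TFs drawn
    uniformly without replacement, observed recomputed, and
    ``p = (1 + #{observed* >= observed}) / (n_perm + 1)``.  ``null='full'``
    additionally resamples which cis-linked TFs carry the knockdown TF's
    footprint (the fuller random-reassignment null).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if null not in ("de", "full"):
        raise ValueError(f"unknown null scheme {null!r}")
    res = oe_ratio(experiment, links, tf_universe)
    nge, ndge, ncis = res.nge, res.ndge, res.ncis
    if ndge > nge:
        raise ValueError("ndge exceeds nge")
    rng = np.random.default_rng(seed)
    out: Dict[str, float] = {}
    for cls in CLASSES:
        cr = res.by_class[cls]
        if null == "de":
            sim = _resample_observed(cr.ncis_tf, nge, ndge, n_perm, rng)
        else:
            # Fuller null: footprinted targets are also re-drawn, uniformly
            # from the cis-linked TFs, before intersecting with the DE draw.
            sim = np.empty(n_perm, dtype=np.int64)
            universe = np.arange(nge)
            for i in range(n_perm):
                de = rng.choice(universe, size=ndge, replace=False)
                cis = rng.choice(universe, size=ncis, replace=False)
                targets = rng.choice(cis, size=cr.ncis_tf, replace=False) \
                    if cr.ncis_tf else np.empty(0, dtype=np.int64)
                sim[i] = np.intersect1d(de, targets).size
        out[cls] = float((1 + int((sim >= cr.observed).sum())) / (n_perm + 1))
        cr.p_perm = out[cls]
    return out


def cohort_summary(
    results: Sequence[LinkEnrichmentResult],
) -> Tuple[Dict[str, Optional[float]], pd.DataFrame]:
    """Cohort mean ratio per class plus the per-knockdown table.

    The mean is taken over knockdowns with a defined ratio only; the
    per-class count of contributing knockdowns is in the table.
    """
    if not results:
        raise ValueError("no results to summarise")
    rows = []
    for r in results:
        row = {"knockdown_tf": r.knockdown_tf, "nge": r.nge, "ndge": r.ndge,
               "ncis": r.ncis}
        for cls in CLASSES:
            cr = r.by_class[cls]
            row[f"ncis_tf_{cls}"] = cr.ncis_tf
            row[f"observed_{cls}"] = cr.observed
            row[f"expected_{cls}"] = cr.expected
            row[f"ratio_{cls}"] = cr.ratio
            row[f"p_perm_{cls}"] = cr.p_perm
        rows.append(row)
    table = pd.DataFrame(rows)
    means: Dict[str, Optional[float]] = {}
    defined_any = False
    for cls in CLASSES:
        ratios = [r.by_class[cls].ratio for r in results
                  if r.by_class[cls].ratio is not None]
        means[cls] = float(np.mean(ratios)) if ratios else None
        defined_any = defined_any or bool(ratios)
    if not defined_any:
        raise ValueError("all ratios undefined; cohort mean is meaningless")
    return means, table
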