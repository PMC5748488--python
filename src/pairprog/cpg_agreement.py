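"""Cross-tissue common-prognostic-gene selection and agreement statistics.

A gene is a common prognostic gene (CPG) when its cutoff scan is significant
in both the tumor (PT) and adjacent-tissue (AT) data of the same patients at
``alpha_pre`` *and* carries the same risk design in both tissues.  Agreement
between the two per-patient stratifications is summarized as a binomial
proportion with a Newcombe/Wilson score confidence interval (continuity-
corrected form; this variant reproduces the published intervals).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import hypergeom, norm
from statsmodels.stats.proportion import proportion_confint

from .data_model import PipelineConfig
from .ddg import GenePrognosis


@dataclass
class AgreementStats:
    k: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float
    conf_level: float


@dataclass
class CPGRecord:
    gene_id: str
    pt: GenePrognosis
    at: GenePrognosis
    shared_design: int
    agreement: AgreementStats | None


def wilson_cc_ci(k: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Continuity-corrected Wilson score interval for a binomial proportion.

    Closed-form solution of the score test with a 1/(2n) continuity term
    (Newcombe's 'efficient score' recommendation).  Bounds are truncated to
    [0, 1]; the lower bound is exactly 0 when k = 0 and the upper exactly 1
    when k = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    z = norm.ppf(1 - (1 - conf_level) / 2)
    p = k / n
    q = 1 - p
    if k == 0:
        low = 0.0
    else:
        low = (2 * n * p + z * z - 1
               - z * math.sqrt(z * z - 2 - 1 / n + 4 * p * (n * q + 1))
               ) / (2 * (n + z * z))
    if k == n:
        high = 1.0
    else:
        high = (2 * n * p + z * z + 1
                + z * math.sqrt(z * z + 2 - 1 / n + 4 * p * (n * q - 1))
                ) / (2 * (n + z * z))
    return max(0.0, low), min(1.0, high)


def agreement_stats(labels_a: Mapping[str, str], labels_b: Mapping[str, str],
                    conf_level: float = 0.95) -> AgreementStats:
    """Concordance of two labelings over an identical patient domain."""
    if set(labels_a) != set(labels_b):
        unmatched = sorted(set(labels_a) ^ set(labels_b))
        raise ValueError(f"label domains differ; unmatched: {unmatched[:10]}")
    n = len(labels_a)
    if n < 1:
        raise ValueError("empty label domain")
    k = sum(labels_a[p] == labels_b[p] for p in labels_a)
    low, high = wilson_cc_ci(k, n, conf_level)
    return AgreementStats(k=k, n=n, proportion=k / n, ci_low=low, ci_high=high,
                          conf_level=conf_level)


def proportion_diff_ci(k1: int, n1: int, k2: int, n2: int,
                       conf_level: float = 0.95,
                       continuity: bool = False) -> tuple[float, float, bool]:
    """Newcombe hybrid score interval for the difference p1 - p2.

    Combines the per-proportion Wilson limits (square-and-add); the default
    follows Newcombe's method 10 (no continuity correction), switchable to
    the continuity-corrected variant.  Returns (low, high, significant) where
    ``significant`` means 0 lies outside the interval.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("n1 and n2 must be >= 1")
        if not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n")
    alpha = 1 - conf_level
    if continuity:
        l1, u1 = wilson_cc_ci(k1, n1, conf_level)
        l2, u2 = wilson_cc_ci(k2, n2, conf_level)
    else:
        l1, u1 = proportion_confint(k1, n1, alpha=alpha, method="wilson")
        l2, u2 = proportion_confint(k2, n2, alpha=alpha, method="wilson")
    p1, p2 = k1 / n1, k2 / n2
    diff = p1 - p2
    low = diff - math.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
    high = diff + math.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    significant = not (low <= 0.0 <= high)
    return low, high, significant


def hypergeom_overlap(set_a: Iterable, set_b: Iterable, universe_size: int) -> float:
    """Upper-tail hypergeometric probability P(X >= |A & B|)."""
    a, b = set(set_a), set(set_b)
    if len(a | b) > universe_size:
        raise ValueError("universe smaller than the union of the two sets")
    overlap = len(a & b)
    if overlap == 0:
        return 1.0
    return float(hypergeom.sf(overlap - 1, universe_size, len(a), len(b)))


def select_cpg(
    pt_results: Mapping[str, GenePrognosis],
    at_results: Mapping[str, GenePrognosis],
    cfg: PipelineConfig,
    pairing: Mapping[str, tuple[str, str | None]] | None = None,
) -> list[CPGRecord]:
    """Genes significant in both tissues at ``alpha_pre`` with identical design.

    When ``pairing`` (patient -> (pt_sample, at_sample)) is supplied, each
    record carries the PT-vs-AT label agreement computed over the patients
    that have both samples.  Symmetric in tissue order for the concordance
    criterion; returned sorted by gene id.
    """
    shared = sorted(set(pt_results) & set(at_results))
    if not shared:
        warnings.warn("disjoint gene sets between PT and AT scans", stacklevel=2)
        return []
    out: list[CPGRecord] = []
    for gene in shared:
        pt, at = pt_results[gene], at_results[gene]
        if pt.design != at.design:
            continue
        if pt.wald_p > cfg.alpha_pre or at.wald_p > cfg.alpha_pre:
            continue
        agreement = None
        if pairing is not None:
            a_lab, b_lab = {}, {}
            for patient, (pt_s, at_s) in pairing.items():
                if at_s is None:
                    continue
                if pt_s in pt.labels and at_s in at.labels:
                    a_lab[patient] = pt.labels[pt_s]
                    b_lab[patient] = at.labels[at_s]
            if a_lab:
                agreement = agreement_stats(a_lab, b_lab, cfg.conf_level)
        out.append(CPGRecord(gene_id=gene, pt=pt, at=at,
                             shared_design=pt.design, agreement=agreement))
    return out


def by_design(records: list[CPGRecord]) -> tuple[list[CPGRecord], list[CPGRecord]]:
    """Partition CPGs into (tumor-suppressor-like, pro-oncogenic) subsets."""
    d1 = [r for r in records if r.shared_design == 1]
    d2 = [r for r in records if r.shared_design == 2]
    return d1, d2
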