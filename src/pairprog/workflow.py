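"""In-memory training/validation workflow used by the CLI and test harnesses.

Chains the pipeline stages on a :class:`~pairprog.data_model.PairedCohort`:
cutoff scans in both tissues, cross-tissue prognostic-gene selection, a
survival-blind co-expression module filter over the selected genes, and the
weighted-voting classifier fit.  Returns the frozen model together with all
intermediate tables.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cpg_agreement import CPGRecord, select_cpg
from .data_model import PairedCohort, PipelineConfig
from .ddg import DDgTable, batch_scan
from .deg_corr import coexpression_module
from .swvg import SWVgModel, StratificationResult, apply_frozen, fit_swvg


@dataclass
class PipelineFit:
    model: SWVgModel
    pt_scan: DDgTable
    at_scan: DDgTable | None
    cpgs: list[CPGRecord]
    candidate_genes: list[str]
    training: StratificationResult


def fit_pipeline(
    cohort: PairedCohort,
    cfg: PipelineConfig,
    *,
    designs: tuple[int, ...] = (1, 2),
    module_filter: bool = True,
    selection: str = "cv",
    statistic: str = "wald",
) -> PipelineFit:
    """Train the full classifier on one paired cohort.

    ``designs`` restricts the cross-tissue gene set by shared risk design
    (the published classifier kept only the pro-oncogenic subset, i.e.
    ``designs=(2,)``).  ``module_filter`` applies the co-expression coherence
    filter; it uses expression structure only, never survival.
    """
    surv_pt = cohort.survival_frame("PT")
    pt_scan = batch_scan(cohort.pt, surv_pt, cfg, tissue="PT",
                         statistic=statistic)
    at_scan = None
    cpgs: list[CPGRecord] = []
    if cohort.at is not None:
        at_scan = batch_scan(cohort.at, cohort.survival_frame("AT"), cfg,
                             tissue="AT", statistic=statistic)
        cpgs = select_cpg(pt_scan.results, at_scan.results, cfg,
                          pairing=cohort.pairing)
        pool = {r.gene_id for r in cpgs if r.shared_design in designs}
    else:
        pool = {g for g, r in pt_scan.results.items() if r.design in designs}
    if module_filter and pool:
        pool = coexpression_module(cohort.pt, pool)
    candidates = {g: pt_scan.results[g] for g in sorted(pool)
                  if pt_scan.results[g].wald_p <= cfg.alpha_sel}
    model = fit_swvg(candidates, cohort.pt, surv_pt, cfg,
                     selection=selection, statistic=statistic,
                     cohort_id="training")
    training = apply_frozen(model, cohort.pt, surv_pt,
                            sample_to_patient=cohort.sample_to_patient(),
                            conf_level=cfg.conf_level, cohort_id="training")
    return PipelineFit(model=model, pt_scan=pt_scan, at_scan=at_scan,
                       cpgs=cpgs, candidate_genes=sorted(candidates),
                       training=training)


def validate_frozen(model: SWVgModel, cohort: PairedCohort,
                    cfg: PipelineConfig, tissue: str = "PT") -> StratificationResult:
    """Apply a frozen model to an independent cohort, blinded to survival
    during labeling; the survival summary is computed post hoc."""
    matrix = cohort.pt if tissue == "PT" else cohort.at
    return apply_frozen(model, matrix, cohort.survival_frame(tissue),
                        sample_to_patient=cohort.sample_to_patient(),
                        conf_level=cfg.conf_level, cohort_id="validation")
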