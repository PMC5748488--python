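"""Statistically weighted voting risk classifier.

Each panel gene casts a binary high-risk vote from its frozen cutoff/design;
votes are combined into a normalized score ``s = sum(w_j v_j) / sum(w_j)``
with weights ``w_j = -log10(training Wald p)``.  Fitting scans panel sizes
over significance-ordered gene prefixes and score cutoffs over admissible
score midpoints, minimizing the Wald p of the resulting two-group survival
split.  The fitted model is frozen (JSON-serializable, bit-exact round trip)
and can be applied to any cohort blinded to its survival data.

The published classifier's unnormalized score cutoff lives on a scale defined
by uncited prior work; the normalized score with a data-optimized cutoff
preserves the voting logic while being self-contained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._cox import BETA_CAP, fit_binary_cox, fit_binary_cox_many
from .data_model import ExpressionMatrix, PipelineConfig
from .ddg import (P_TIE_RTOL, GenePrognosis, _p_per_cutoff, _pick_cutoff,
                  candidate_cutoffs)

#: floor applied to training p-values before taking -log10
P_FLOOR = 1e-300


class DegenerateScores(ValueError):
    """All candidate score vectors are constant; no classifier can be fit."""


@dataclass
class PanelGene:
    gene_id: str
    cutoff: float
    design: int
    weight: float
    probe_id: str | None = None
    train_wald_p: float | None = None


@dataclass
class SWVgModel:
    """Frozen multigene risk classifier."""

    genes: list[PanelGene]
    score_cutoff: float
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty gene panel")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate panel genes")
        if any(g.weight < 0 for g in self.genes):
            raise ValueError("negative weight")
        if not any(g.weight > 0 for g in self.genes):
            raise ValueError("all weights zero")
        if not (0 < self.score_cutoff < 1):
            raise ValueError("score_cutoff must lie in (0, 1)")
        for g in self.genes:
            if g.design not in (1, 2) or not np.isfinite(g.cutoff):
                raise ValueError(f"invalid panel entry for {g.gene_id}")

    def to_dict(self) -> dict:
        return {
            "genes": [{"gene_id": g.gene_id, "probe_id": g.probe_id,
                       "cutoff": g.cutoff, "design": g.design,
                       "weight": g.weight, "train_wald_p": g.train_wald_p}
                      for g in self.genes],
            "score_cutoff": self.score_cutoff,
            "training_meta": self.training_meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SWVgModel":
        genes = [PanelGene(**g) for g in d["genes"]]
        return cls(genes=genes, score_cutoff=d["score_cutoff"],
                   training_meta=d.get("training_meta", {}))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SWVgModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class StratificationResult:
    """Per-sample scores/labels plus an optional post-hoc survival summary."""

    assignments: pd.DataFrame          # index sample_id; score, label, patient_id
    summary: dict | None
    flagged: list[str]
    provenance: dict = field(default_factory=dict)

    def labels_by_patient(self) -> dict[str, str]:
        ok = self.assignments.dropna(subset=["label"])
        return dict(zip(ok["patient_id"], ok["label"]))


def gene_vote(expr_value: float, cutoff: float, design: int) -> int:
    """1 = this gene votes high-risk.  Values exactly at the cutoff fall on
    the <= side (consistent with cutoff-scan labeling)."""
    above = expr_value > cutoff
    return int(above if design == 2 else not above)


def swvg_score(votes: np.ndarray, weights: np.ndarray) -> np.ndarray | float:
    """Normalized weighted vote, in [0, 1]."""
    votes = np.asarray(votes, dtype=float)
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("sum of weights must be positive")
    return votes @ weights / total


def _votes_matrix(matrix: ExpressionMatrix, genes: list[PanelGene],
                  sample_ids: list[str]) -> np.ndarray:
    """(n_samples, n_genes) high-risk votes; NaN rows propagate."""
    sub = matrix.subset_genes([g.gene_id for g in genes]).subset_samples(sample_ids)
    vals = sub.values.T                                    # samples x genes
    votes = np.empty_like(vals)
    for j, g in enumerate(genes):
        above = vals[:, j] > g.cutoff
        votes[:, j] = above if g.design == 2 else ~above
    return votes


def _best_score_split(scores: np.ndarray, times: np.ndarray, events: np.ndarray,
                      cfg: PipelineConfig, statistic: str) -> tuple[float, float] | None:
    """(best p, cutoff) for a score vector, or None if degenerate."""
    grid = candidate_cutoffs(scores, cfg)
    if grid.size == 0:
        return None
    fits = fit_binary_cox_many(times, events, scores[:, None] > grid[None, :])
    p = _p_per_cutoff(fits, statistic)
    if not np.isfinite(p).any():
        return None
    idx = _pick_cutoff(p, grid, float(np.median(scores)))
    return float(p[idx]), float(grid[idx])


def _scan_selection(votes: np.ndarray, weights: np.ndarray,
                    times: np.ndarray, events: np.ndarray,
                    cfg: PipelineConfig, statistic: str):
    """(best p, cutoff) per prefix size over a vote matrix; None if degenerate."""
    weighted_cum = np.cumsum(votes * weights[None, :], axis=1)
    wsum = np.cumsum(weights)
    out = []
    for m in range(1, votes.shape[1] + 1):
        scores = weighted_cum[:, m - 1] / wsum[m - 1]
        out.append((_best_score_split(scores, times, events, cfg, statistic),
                    scores))
    return out


def _oof_scores(ordered: list[GenePrognosis], matrix: ExpressionMatrix,
                common: list[str], times: np.ndarray, events: np.ndarray,
                cfg: PipelineConfig, statistic: str, n_folds: int) -> np.ndarray:
    """Out-of-fold vote matrix: gene cutoffs/designs/weights are refit without
    each held-out fold, so the held-out votes carry no survival leak."""
    from .ddg import NoValidCutoff, scan_cutoff

    n = len(common)
    rng = np.random.default_rng(cfg.seed)
    fold = rng.permutation(n) % n_folds
    sub = matrix.subset_samples(common)
    gene_rows = {r.gene_id: sub.gene_ids.index(r.gene_id) for r in ordered}
    votes = np.zeros((n, len(ordered)))
    wmat = np.zeros((n, len(ordered)))
    for f in range(n_folds):
        test = fold == f
        train = ~test
        for j, r in enumerate(ordered):
            vals = sub.values[gene_rows[r.gene_id]]
            try:
                fit = scan_cutoff(vals[train], times[train], events[train],
                                  cfg, gene_id=r.gene_id, statistic=statistic)
                cutoff, design, w = fit.cutoff, fit.design, \
                    float(-np.log10(max(fit.wald_p, P_FLOOR)))
            except NoValidCutoff:
                cutoff, design, w = r.cutoff, r.design, 1.0  # rare fallback
            above = vals[test] > cutoff
            votes[test, j] = above if design == 2 else ~above
            wmat[test, j] = w
    return votes, wmat


def fit_swvg(
    candidates: Mapping[str, GenePrognosis],
    matrix: ExpressionMatrix,
    surv: pd.DataFrame,
    cfg: PipelineConfig,
    *,
    statistic: str = "wald",
    selection: str = "cv",
    n_folds: int = 5,
    cv_band: float = 30.0,
    cohort_id: str = "",
    probe_ids: Mapping[str, str] | None = None,
) -> SWVgModel:
    """Fit the weighted-voting classifier on training data.

    ``candidates`` are per-gene cutoff-scan results; genes failing
    ``alpha_sel`` are dropped.  Genes are ordered by ascending training p
    (ties by gene id); for every prefix size the best admissible score cutoff
    is found, and the (size, cutoff) pair minimizing the split's p wins
    (ties: smaller panel).

    ``selection`` controls where that p is measured:

    * ``"cv"`` (default): panel size and score cutoff are chosen on pooled
      out-of-fold scores (per-gene cutoffs refit within each of ``n_folds``
      training folds, seeded by ``cfg.seed``).  In-sample selection provably
      absorbs the survival noise already baked into the per-gene cutoffs and
      picks large, poorly transferring panels; out-of-fold selection restores
      parameter recovery while leaving the frozen-model semantics unchanged.
    * ``"insample"``: the literal training-data scan.
    """
    if selection not in ("cv", "insample"):
        raise ValueError("selection must be 'cv' or 'insample'")
    cand = {g: r for g, r in candidates.items()
            if r.wald_p <= cfg.alpha_sel and g in matrix.gene_ids}
    if not cand:
        raise ValueError(f"no candidate gene passes alpha_sel={cfg.alpha_sel}")
    ordered = sorted(cand.values(), key=lambda r: (r.wald_p, r.gene_id))

    common = [s for s in matrix.sample_ids if s in surv.index]
    if not common:
        raise ValueError("no overlapping samples between matrix and survival")
    times = surv.loc[common, "os_years"].to_numpy(float)
    events = surv.loc[common, "event"].to_numpy(float)

    panel = [PanelGene(
        gene_id=r.gene_id, cutoff=r.cutoff, design=r.design,
        weight=float(-np.log10(max(r.wald_p, P_FLOOR))),
        probe_id=(probe_ids or {}).get(r.gene_id),
        train_wald_p=r.wald_p) for r in ordered]
    weights = np.array([g.weight for g in panel])

    if selection == "cv" and len(common) >= 2 * n_folds:
        votes, wmat = _oof_scores(ordered, matrix, common, times, events, cfg,
                                  statistic, n_folds)
        # per-sample weight normalization (fold weights differ slightly)
        cum = np.cumsum(votes * wmat, axis=1)
        wnorm = np.maximum(np.cumsum(wmat, axis=1), 1e-12)
        splits = []
        for m in range(1, votes.shape[1] + 1):
            scores = cum[:, m - 1] / wnorm[:, m - 1]
            splits.append((_best_score_split(scores, times, events, cfg,
                                             statistic), scores))
    else:
        ins = _votes_matrix(matrix, panel, common)
        splits = _scan_selection(ins, weights, times, events, cfg, statistic)

    trace = []
    usable = []                        # (m, p, cutoff)
    for m, (res, _) in enumerate(splits, start=1):
        if res is None:
            trace.append({"panel_size": m, "wald_p": None, "score_cutoff": None})
            continue
        p, cutoff = res
        trace.append({"panel_size": m, "wald_p": p, "score_cutoff": cutoff})
        usable.append((m, p, cutoff))
    if not usable:
        raise DegenerateScores("all candidate score vectors are degenerate")
    pmin = min(p for _, p, _ in usable)
    if selection == "cv" and len(common) >= 2 * n_folds:
        # out-of-fold p values within a small factor (``cv_band``) of the
        # optimum are Monte-Carlo-indistinguishable: take the largest such
        # panel (more votes average out per-gene noise) ...
        band = [(m, p, c) for m, p, c in usable
                if p <= pmin * cv_band * (1 + P_TIE_RTOL)]
        m_best, p_best, cutoff_best = band[-1]
        # ... but collapse exact ties downward (adding genes that change
        # nothing must not grow the panel)
        for m, p, c in band:
            if abs(p - p_best) <= P_TIE_RTOL * max(p_best, 1e-300):
                m_best, cutoff_best = m, c
                break
    else:
        # literal rule: minimum p, ties to the smaller panel
        exact = [(m, p, c) for m, p, c in usable
                 if p <= pmin + P_TIE_RTOL * max(pmin, 1e-300)]
        m_best, _, cutoff_best = exact[0]

    if selection == "cv" and len(common) >= 2 * n_folds:
        # translate the out-of-fold cutoff onto the frozen model's score scale:
        # keep the quantile position of the chosen split
        _, oof_scores = splits[m_best - 1]
        frac_le = float(np.mean(oof_scores <= cutoff_best))
        final_scores = np.asarray(swvg_score(
            _votes_matrix(matrix, panel[:m_best], common), weights[:m_best]))
        grid = candidate_cutoffs(final_scores, cfg)
        if grid.size:
            below = np.array([np.mean(final_scores <= c) for c in grid])
            cutoff_best = float(grid[int(np.argmin(np.abs(below - frac_le)))])
        else:
            cutoff_best = 0.5

    return SWVgModel(
        genes=panel[:m_best],
        score_cutoff=cutoff_best,
        training_meta={
            "cohort_id": cohort_id,
            "alpha_sel": cfg.alpha_sel,
            "statistic": statistic,
            "selection": selection,
            "n_candidates": len(panel),
            "n_train_samples": len(common),
            "selection_trace": trace,
        },
    )


def apply_frozen(
    model: SWVgModel,
    matrix: ExpressionMatrix,
    surv: pd.DataFrame | None = None,
    *,
    conf_level: float = 0.95,
    sample_to_patient: Mapping[str, str] | None = None,
    cohort_id: str = "",
) -> StratificationResult:
    """Apply a frozen model; labels depend on expression alone.

    Samples with a missing (NaN handled upstream as parse errors, but scores
    can be NaN through subsetting) panel-gene value are flagged and excluded
    from the post-hoc summary.  If ``surv`` is given, a two-group
    proportional-hazards summary (HR of HR vs LR, CI, Wald p) is added.
    """
    missing = [g.gene_id for g in model.genes if g.gene_id not in matrix.gene_ids]
    if missing:
        raise KeyError(f"matrix is missing panel genes: {missing}")
    samples = list(matrix.sample_ids)
    votes = _votes_matrix(matrix, model.genes, samples)
    weights = np.array([g.weight for g in model.genes])
    scores = np.asarray(swvg_score(votes, weights), dtype=float)
    labels = np.where(scores > model.score_cutoff, "HR", "LR").astype(object)
    flagged = [s for s, sc in zip(samples, scores) if not np.isfinite(sc)]
    for i, s in enumerate(samples):
        if s in flagged:
            labels[i] = None
    s2p = dict(sample_to_patient or {})
    assignments = pd.DataFrame({
        "score": scores,
        "label": labels,
        "patient_id": [s2p.get(s, s) for s in samples],
    }, index=pd.Index(samples, name="sample_id"))

    summary = None
    if surv is not None:
        ok = assignments.dropna(subset=["label"])
        ok = ok.loc[[s for s in ok.index if s in surv.index]]
        hr_mask = (ok["label"] == "HR").to_numpy()
        n_hr, n_lr = int(hr_mask.sum()), int((~hr_mask).sum())
        summary = {"n_lr": n_lr, "n_hr": n_hr, "hazard_ratio": None,
                   "ci": (None, None), "wald_p": None, "logrank_p": None}
        if 0 < n_hr < len(ok):
            times = surv.loc[ok.index, "os_years"].to_numpy(float)
            events = surv.loc[ok.index, "event"].to_numpy(float)
            fit = fit_binary_cox(times, events, hr_mask)
            z = norm.ppf(1 - (1 - conf_level) / 2)
            beta = float(fit.beta[0])
            summary["hazard_ratio"] = float(np.exp(min(abs(beta), BETA_CAP))
                                            if fit.separated[0] else np.exp(beta))
            summary["logrank_p"] = float(fit.score_p[0])
            if fit.converged[0]:
                se = float(fit.se[0])
                summary["ci"] = (float(np.exp(beta - z * se)),
                                 float(np.exp(beta + z * se)))
                summary["wald_p"] = float(fit.wald_p[0])
            else:
                summary["wald_p"] = float(fit.score_p[0])  # log-rank fallback
    return StratificationResult(
        assignments=assignments, summary=summary, flagged=flagged,
        provenance={"cohort_id": cohort_id,
                    "model_genes": [g.gene_id for g in model.genes],
                    "score_cutoff": model.score_cutoff},
    )


def combine_pt_at(strat_t: StratificationResult,
                  strat_a: StratificationResult) -> pd.Series:
    """Conjunction stratification: LR iff LR in both tissues.

    Defined on the intersection of the two patient sets; exact set identity
    ``LR_combined = LR_T & LR_A`` holds by construction.
    """
    lab_t = strat_t.labels_by_patient()
    lab_a = strat_a.labels_by_patient()
    patients = sorted(set(lab_t) & set(lab_a))
    if not patients:
        raise ValueError("no patients shared between PT and AT stratifications")
    combined = {p: ("LR" if lab_t[p] == "LR" and lab_a[p] == "LR" else "HR")
                for p in patients}
    return pd.Series(combined, name="label").rename_axis("patient_id")


def load_ribosomal_panel() -> pd.DataFrame:
    """Packaged 24-gene ribosomal prognostic panel (gene symbol, probe id)."""
    with resources.files("pairprog.resources").joinpath(
            "ribosomal_panel_24.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
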