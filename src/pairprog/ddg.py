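"""Per-gene survival-optimal expression dichotomization (1-D grouping).

For one gene, every admissible cutoff between consecutive distinct expression
values is evaluated by a univariate proportional-hazards fit on the binary
above/below indicator; the cutoff minimizing the Wald p-value is retained.
The direction of the fitted effect assigns the risk design:

* design 2 (pro-oncogenic): expression above the cutoff marks the high-risk
  (HR) group;
* design 1 (tumor-suppressor-like): expression above the cutoff marks the
  low-risk (LR) group.

Selecting the minimum p over many cutoffs is anti-conservative; the raw
minimum p is what downstream thresholds consume (matching the source method),
and :func:`permutation_adjust` offers a selection-bias-corrected p on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cox import BETA_CAP, fit_binary_cox_many
from .data_model import ExpressionMatrix, PipelineConfig

#: relative tolerance under which two p-values count as tied
P_TIE_RTOL = 1e-9


class NoValidCutoff(ValueError):
    """No admissible cutoff yields a usable survival split."""


@dataclass
class GenePrognosis:
    """Frozen result of a single-gene cutoff scan."""

    gene_id: str
    tissue: str
    cutoff: float
    design: int
    wald_p: float
    hazard_ratio: float
    labels: dict[str, str]
    n_lr: int
    n_hr: int
    fallback_logrank: bool = False
    n_cutoffs_skipped: int = 0
    extras: dict = field(default_factory=dict)

    def apply_labels(self, values: np.ndarray, sample_ids: list[str]) -> dict[str, str]:
        """Re-apply the stored (cutoff, design) to expression values."""
        above = np.asarray(values, dtype=float) > self.cutoff
        hr = above if self.design == 2 else ~above
        return {s: ("HR" if h else "LR") for s, h in zip(sample_ids, hr)}


def candidate_cutoffs(values: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Midpoints between consecutive distinct values leaving an admissible
    number of samples (>= max(min_group_size, ceil(min_group_fraction*n)))
    on each side."""
    values = np.asarray(values, dtype=float)
    n = values.size
    u = np.unique(values)
    if u.size < 2:
        return np.empty(0)
    mids = (u[:-1] + u[1:]) / 2.0
    below = np.searchsorted(np.sort(values), mids)
    m = cfg.min_side(n)
    return mids[(below >= m) & (n - below >= m)]


def _p_per_cutoff(fits, statistic: str) -> np.ndarray:
    """Selection p per cutoff, with log-rank fallback under separation."""
    if statistic == "logrank":
        return np.where(fits.valid, fits.score_p, np.nan)
    p = np.where(fits.converged, fits.wald_p, np.nan)
    # monotone likelihood: Wald statistic is meaningless, use the score test
    return np.where(fits.separated, fits.score_p, p)


def _pick_cutoff(p: np.ndarray, grid: np.ndarray, median: float) -> int:
    """Index of the minimum p; ties resolve to the cutoff closest to the
    sample median, then to the smaller cutoff."""
    pmin = np.nanmin(p)
    tied = np.flatnonzero(np.isfinite(p) & (p <= pmin + P_TIE_RTOL * max(pmin, 1e-300)))
    dist = np.abs(grid[tied] - median)
    best = tied[np.lexsort((grid[tied], dist))]
    return int(best[0])


def scan_cutoff(
    values: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    cfg: PipelineConfig,
    *,
    gene_id: str = "",
    tissue: str = "PT",
    sample_ids: list[str] | None = None,
    statistic: str = "wald",
) -> GenePrognosis:
    """Scan all admissible cutoffs for one gene and freeze the best split.

    ``statistic`` is ``"wald"`` (default; Wald test of the binary indicator
    in a proportional-hazards fit, Efron ties) or ``"logrank"`` (score test).
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    n = values.size
    if times.size != n or events.size != n:
        raise ValueError("expression and survival arrays must align")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite expression values")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    if n < 2 * cfg.min_group_size:
        raise NoValidCutoff(f"{gene_id or 'gene'}: only {n} samples")

    grid = candidate_cutoffs(values, cfg)
    if grid.size == 0:
        raise NoValidCutoff(f"{gene_id or 'gene'}: no admissible cutoff "
                            "(constant or near-constant expression)")
    X = values[:, None] > grid[None, :]
    fits = fit_binary_cox_many(times, events, X)
    p = _p_per_cutoff(fits, statistic)
    n_skipped = int(np.sum(~np.isfinite(p)))
    if not np.isfinite(p).any():
        raise NoValidCutoff(f"{gene_id or 'gene'}: all cutoffs unusable "
                            "(no events or degenerate fits)")
    if n_skipped:
        warnings.warn(f"{gene_id or 'gene'}: {n_skipped} cutoffs skipped "
                      "(non-convergent or uninformative fits)", stacklevel=2)

    idx = _pick_cutoff(p, grid, float(np.median(values)))
    beta = fits.beta[idx]
    design = 2 if beta > 0 else 1
    hr = float(np.exp(min(abs(beta), BETA_CAP)))
    above = values > grid[idx]
    hr_mask = above if design == 2 else ~above
    labels = {s: ("HR" if h else "LR") for s, h in zip(sample_ids, hr_mask)}
    return GenePrognosis(
        gene_id=gene_id, tissue=tissue, cutoff=float(grid[idx]), design=design,
        wald_p=float(p[idx]), hazard_ratio=hr, labels=labels,
        n_lr=int(np.sum(~hr_mask)), n_hr=int(np.sum(hr_mask)),
        fallback_logrank=bool(fits.separated[idx]) and statistic == "wald",
        n_cutoffs_skipped=n_skipped,
        extras={"beta": float(beta), "n_cutoffs": int(grid.size)},
    )


def min_p(values, times, events, cfg, statistic: str = "wald") -> float:
    """Minimum selection p over the cutoff grid (NaN if no usable cutoff)."""
    grid = candidate_cutoffs(np.asarray(values, float), cfg)
    if grid.size == 0:
        return float("nan")
    X = np.asarray(values, float)[:, None] > grid[None, :]
    fits = fit_binary_cox_many(times, events, X)
    p = _p_per_cutoff(fits, statistic)
    return float(np.nanmin(p)) if np.isfinite(p).any() else float("nan")


def permutation_filter(
    table: "DDgTable",
    matrix: ExpressionMatrix,
    surv: pd.DataFrame,
    cfg: PipelineConfig,
    alpha: float,
    n_perm: int = 100,
    seed: int = 0,
    *,
    statistic: str = "wald",
) -> dict[str, tuple[GenePrognosis, float]]:
    """Keep genes whose selection-bias-adjusted p passes ``alpha``.

    Runs :func:`permutation_adjust` on every gene of a scan table (one seeded
    stream per gene, derived from ``seed``) and returns
    ``gene -> (GenePrognosis, adjusted_p)`` for the survivors.  This is the
    guard against the min-p selection bias that raw thresholds ignore.
    """
    common = [s for s in matrix.sample_ids if s in surv.index]
    sub = matrix.subset_samples(common)
    times = surv.loc[common, "os_years"].to_numpy(float)
    events = surv.loc[common, "event"].to_numpy(float)
    root = np.random.default_rng(seed)
    out: dict[str, tuple[GenePrognosis, float]] = {}
    for gene, res in table.results.items():
        gene_seed = int(root.integers(2**63))
        if gene not in sub.gene_ids:
            continue
        if res.wald_p > alpha:
            continue    # adjusted p can only be (weakly) larger in practice
        adj = permutation_adjust(res, sub.values[sub.gene_ids.index(gene)],
                                 times, events, cfg, n_perm, gene_seed,
                                 statistic=statistic)
        if adj <= alpha:
            out[gene] = (res, adj)
    return out


@dataclass
class DDgTable:
    """Batch scan output: per-gene results plus the degenerate remainder."""

    results: dict[str, GenePrognosis]
    degenerate: dict[str, str]
    tissue: str

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g.gene_id, "tissue": g.tissue, "cutoff": g.cutoff,
             "design": g.design, "wald_p": g.wald_p,
             "hazard_ratio": g.hazard_ratio, "n_lr": g.n_lr, "n_hr": g.n_hr}
            for g in self.results.values()
        ]
        return pd.DataFrame(rows, columns=["gene_id", "tissue", "cutoff", "design",
                                           "wald_p", "hazard_ratio", "n_lr", "n_hr"])

    def significant(self, alpha: float) -> dict[str, GenePrognosis]:
        return {g: r for g, r in self.results.items() if r.wald_p <= alpha}


def batch_scan(
    matrix: ExpressionMatrix,
    surv: pd.DataFrame,
    cfg: PipelineConfig,
    *,
    tissue: str = "PT",
    statistic: str = "wald",
) -> DDgTable:
    """Run :func:`scan_cutoff` over every gene of a matrix.

    ``surv`` is indexed by sample id with columns ``os_years`` and ``event``;
    only samples present in both inputs are scored.  Deterministic.
    """
    common = [s for s in matrix.sample_ids if s in surv.index]
    if not common:
        raise ValueError("no overlapping samples between matrix and survival")
    sub = matrix.subset_samples(common)
    times = surv.loc[common, "os_years"].to_numpy(float)
    events = surv.loc[common, "event"].to_numpy(float)
    results: dict[str, GenePrognosis] = {}
    degenerate: dict[str, str] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, gene in enumerate(sub.gene_ids):
            try:
                results[gene] = scan_cutoff(
                    sub.values[i], times, events, cfg, gene_id=gene,
                    tissue=tissue, sample_ids=common, statistic=statistic)
            except NoValidCutoff as exc:
                degenerate[gene] = str(exc)
    return DDgTable(results=results, degenerate=degenerate, tissue=tissue)


def permutation_adjust(
    gene_result: GenePrognosis,
    values: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    cfg: PipelineConfig,
    n_perm: int,
    seed: int,
    *,
    statistic: str = "wald",
) -> float:
    """Selection-bias-corrected p for a scanned gene.

    Permutes the (time, event) pairs jointly against expression, recomputes
    the minimum p over the (fixed) cutoff grid for each permutation, and
    returns ``(1 + #{min-p_perm <= min-p_obs}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    observed = gene_result.wald_p
    grid = candidate_cutoffs(values, cfg)
    if grid.size == 0:
        raise NoValidCutoff("no admissible cutoff for permutation null")
    rng = np.random.default_rng(seed)
    # permuting (time, event) jointly against expression is equivalent to
    # permuting the expression vector against fixed survival, which lets all
    # permutations share one vectorized fit (grid is permutation-invariant)
    n = values.size
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    X = (values[perms][:, :, None] > grid[None, None, :])      # (P, n, C)
    X = X.transpose(1, 0, 2).reshape(n, n_perm * grid.size)
    fits = fit_binary_cox_many(times, events, X)
    p = _p_per_cutoff(fits, statistic).reshape(n_perm, grid.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        perm_min = np.nanmin(p, axis=1)                        # NaN: all unusable
    count = int(np.sum(perm_min[np.isfinite(perm_min)] <= observed))
    return (1 + count) / (n_perm + 1)
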