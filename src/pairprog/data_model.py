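"""Core data structures and text readers/writers.

Expression matrices are tab-separated text with genes in rows (first column
gene id) and samples in columns.  Clinical tables are tab-separated with
mandatory columns ``sample_id, patient_id, tissue, os_years, event``; any
extra column is kept as a covariate.  Values are assumed to be already
normalized, log2-scale intensities; preprocessing is out of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

TISSUES = ("PT", "AT")


class ParseError(ValueError):
    """Malformed input file; message names the offending row/column."""


class PairingError(ValueError):
    """Inconsistent patient/sample pairing."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    probe_provenance: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) == 0 or len(self.sample_ids) == 0:
            raise ValueError("expression matrix must be non-empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if any(not g for g in self.gene_ids) or any(not s for s in self.sample_ids):
            raise ValueError("empty identifier")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids),
                                self.values[:, idx])

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids),
                                self.values[idx, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, frame.index)), list(map(str, frame.columns)),
                   frame.to_numpy(dtype=np.float64))


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Parse a genes x samples TSV; duplicated gene-id rows are collapsed.

    Among duplicate rows of the same id, the row with the largest variance
    across samples is retained (ties: first occurrence).
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # noqa: BLE001 - reported as parse error
        raise ParseError(f"{path}: cannot parse header/body: {exc}") from exc
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ParseError(f"{path}: empty expression matrix")
    if raw.columns.isnull().any() or (raw.columns.astype(str) == "").any():
        raise ParseError(f"{path}: malformed header (empty sample id)")
    probe = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(probe.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ParseError(
            f"{path}: non-numeric cell at gene {raw.index[r]!r}, "
            f"column {raw.columns[c]!r} (value {raw.iat[r, c]!r})"
        )
    numeric = raw.astype(np.float64)  # exact strtod parse (bit round-trip)
    numeric.index = numeric.index.astype(str)
    if numeric.index.duplicated().any():
        keep_rows = []
        for gid, grp in numeric.groupby(level=0, sort=False):
            keep_rows.append(grp.iloc[int(np.argmax(grp.var(axis=1).to_numpy()))])
        numeric = pd.DataFrame(keep_rows)
        numeric = numeric.loc[~numeric.index.duplicated()]
    return ExpressionMatrix.from_frame(numeric)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    # shortest-repr float formatting round-trips bit-exactly
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def collapse_probes(matrix: ExpressionMatrix,
                    probe_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene symbol.

    Among the probes of a gene the probe with the largest variance across
    samples is retained; ties break to the lexicographically smallest probe
    id.  The chosen probe of each gene is recorded in ``probe_provenance``.
    Idempotent: applying a symbol->symbol identity mapping is a no-op.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    missing = [p for p in matrix.gene_ids if p not in probe_to_gene]
    if missing:
        raise ValueError(f"probes without gene mapping: {missing[:5]}")
    variances = matrix.values.var(axis=1)
    best: dict[str, tuple[float, str, int]] = {}
    for i, probe in enumerate(matrix.gene_ids):
        gene = str(probe_to_gene[probe])
        key = (-variances[i], probe)
        if gene not in best or key < best[gene][:2]:
            best[gene] = (-variances[i], probe, i)
    genes = sorted(best)
    rows = [best[g][2] for g in genes]
    provenance = {g: best[g][1] for g in genes}
    return ExpressionMatrix(genes, list(matrix.sample_ids),
                            matrix.values[rows, :],
                            probe_provenance=provenance)


@dataclass
class SurvivalRecord:
    """One sample's clinical row; survival fields are patient-level."""

    sample_id: str
    patient_id: str
    tissue: str
    os_years: float
    event: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if not (self.os_years >= 0 and math.isfinite(self.os_years)):
            raise ValueError(f"os_years must be finite and >= 0, got {self.os_years}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


CLINICAL_COLUMNS = ["sample_id", "patient_id", "tissue", "os_years", "event"]


def read_clinical(path: str | Path) -> list[SurvivalRecord]:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory columns {missing}")
    extra = [c for c in table.columns if c not in CLINICAL_COLUMNS]
    records = []
    for i, row in table.iterrows():
        try:
            cov = {}
            for c in extra:
                v = row[c]
                if pd.isna(v):
                    continue
                try:
                    cov[c] = float(v)
                except ValueError:
                    cov[c] = v
            records.append(SurvivalRecord(
                sample_id=str(row["sample_id"]),
                patient_id=str(row["patient_id"]),
                tissue=str(row["tissue"]),
                os_years=float(row["os_years"]),
                event=int(float(row["event"])),
                covariates=cov,
            ))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: row {i + 2}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no clinical records")
    return records


def write_clinical(records: list[SurvivalRecord], path: str | Path) -> None:
    cov_names = sorted({k for r in records for k in r.covariates})
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "patient_id": r.patient_id,
               "tissue": r.tissue, "os_years": r.os_years, "event": r.event}
        for c in cov_names:
            row[c] = r.covariates.get(c, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def pair_samples(records: list[SurvivalRecord]) -> dict[str, tuple[str, str | None]]:
    """Build patient -> (pt_sample, at_sample or None).

    Patients with an AT but no PT sample are excluded with a warning.
    Duplicate PT (or AT) samples for one patient are an error.
    """
    if not records:
        raise PairingError("no survival records to pair")
    pt: dict[str, str] = {}
    at: dict[str, str] = {}
    dup = []
    for r in records:
        store = pt if r.tissue == "PT" else at
        if r.patient_id in store:
            dup.append(r.patient_id)
        else:
            store[r.patient_id] = r.sample_id
    if dup:
        raise PairingError(f"duplicate tissue samples for patients: {sorted(set(dup))}")
    orphans = sorted(set(at) - set(pt))
    if orphans:
        warnings.warn(f"excluding {len(orphans)} patients with AT but no PT: "
                      f"{orphans[:5]}", stacklevel=2)
    return {p: (s, at.get(p)) for p, s in pt.items()}


@dataclass
class PairedCohort:
    """Paired PT/AT expression plus patient-level survival."""

    pt: ExpressionMatrix
    at: ExpressionMatrix | None
    records: list[SurvivalRecord]
    pairing: dict[str, tuple[str, str | None]]

    def __post_init__(self) -> None:
        by_sample = {r.sample_id: r for r in self.records}
        pt_samples = set(self.pt.sample_ids)
        at_samples = set(self.at.sample_ids) if self.at is not None else set()
        for patient, (pt_s, at_s) in self.pairing.items():
            if pt_s not in pt_samples:
                raise PairingError(f"PT sample {pt_s!r} of patient {patient!r} "
                                   "not in PT matrix")
            if pt_s not in by_sample:
                raise PairingError(f"PT sample {pt_s!r} has no clinical record")
            if at_s is not None:
                if at_s not in at_samples:
                    raise PairingError(f"AT sample {at_s!r} of patient {patient!r} "
                                       "not in AT matrix")
                if at_s not in by_sample:
                    raise PairingError(f"AT sample {at_s!r} has no clinical record")
                a, b = by_sample[pt_s], by_sample[at_s]
                if (a.os_years, a.event) != (b.os_years, b.event):
                    raise PairingError(
                        f"patient {patient!r}: PT/AT survival disagrees")

    def survival_frame(self, tissue: str = "PT") -> pd.DataFrame:
        """Survival table (os_years, event, patient_id) indexed by sample id."""
        rows = {r.sample_id: (r.os_years, r.event, r.patient_id)
                for r in self.records if r.tissue == tissue}
        frame = pd.DataFrame.from_dict(rows, orient="index",
                                       columns=["os_years", "event", "patient_id"])
        frame.index.name = "sample_id"
        return frame

    def paired_patients(self) -> list[str]:
        return [p for p, (_, a) in self.pairing.items() if a is not None]

    def sample_to_patient(self) -> dict[str, str]:
        return {r.sample_id: r.patient_id for r in self.records}


@dataclass
class PipelineConfig:
    """Thresholds and knobs shared across pipeline stages."""

    alpha_pre: float = 0.1
    alpha_sel: float = 0.05
    min_group_fraction: float = 0.1
    min_group_size: int = 5
    deg_q: float = 0.05
    conf_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha_sel <= self.alpha_pre < 1):
            raise ValueError("need 0 < alpha_sel <= alpha_pre < 1")
        if not (0 < self.min_group_fraction < 0.5):
            raise ValueError("need 0 < min_group_fraction < 0.5")
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        if not (0 < self.deg_q < 1):
            raise ValueError("need 0 < deg_q < 1")
        if not (0.5 < self.conf_level < 1):
            raise ValueError("need 0.5 < conf_level < 1")

    def min_side(self, n: int) -> int:
        """Minimum samples required on each side of a cutoff for n samples."""
        return max(self.min_group_size, math.ceil(self.min_group_fraction * n))

    def with_(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)
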