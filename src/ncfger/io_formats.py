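"""Labeled matrix containers and delimited-text I/O.

Three matrix kinds flow through the pipeline: a cell-line x drug response
matrix with an explicit observed-mask (log IC50 or activity area), a
genes x cell-lines expression matrix, and a drugs x bits binary fingerprint
matrix.  Orientation is fixed; silent transposition is a classic source of
irreproducible joins, so labels are matched exactly and case-sensitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("ncfger")

#: Tokens treated as missing in response files (case-insensitive).
MISSING_TOKENS = frozenset({"", "na", "nan"})


def _check_unique(labels, what: str) -> list[str]:
    labels = [str(x) for x in labels]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)
    return labels


@dataclass
class ResponseMatrix:
    """m x n drug-response matrix with an explicit observed mask.

    ``values`` holds NaN at unobserved entries; ``observed`` is
    authoritative.  Every statistic in the package excludes unobserved
    entries.
    """

    cell_line_ids: list[str]
    drug_ids: list[str]
    values: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.cell_line_ids = _check_unique(self.cell_line_ids, "cell-line")
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        m, n = len(self.cell_line_ids), len(self.drug_ids)
        if self.values.shape != (m, n) or self.observed.shape != (m, n):
            raise ValueError(
                f"shape mismatch: {self.values.shape} values, "
                f"{self.observed.shape} mask, {m} cell lines x {n} drugs"
            )
        if not np.isfinite(self.values[self.observed]).all():
            raise ValueError("non-finite value at an observed entry")
        self.values = np.where(self.observed, self.values, np.nan)

    @classmethod
    def from_array(cls, values, cell_line_ids=None, drug_ids=None) -> "ResponseMatrix":
        """Build from a dense array using NaN as the missing marker."""
        values = np.asarray(values, dtype=float)
        m, n = values.shape
        if cell_line_ids is None:
            cell_line_ids = [f"CL{u}" for u in range(m)]
        if drug_ids is None:
            drug_ids = [f"D{i}" for i in range(n)]
        return cls(list(cell_line_ids), list(drug_ids), values, ~np.isnan(values))

    @property
    def m(self) -> int:
        return len(self.cell_line_ids)

    @property
    def n(self) -> int:
        return len(self.drug_ids)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(
            list(self.cell_line_ids),
            list(self.drug_ids),
            self.values.copy(),
            self.observed.copy(),
        )

    def mask_entries(self, entries: np.ndarray) -> "ResponseMatrix":
        """Return a copy with the given (row, col) index pairs unobserved."""
        out = self.copy()
        rows, cols = np.asarray(entries).T
        out.observed[rows, cols] = False
        out.values[rows, cols] = np.nan
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_line_ids, columns=self.drug_ids)


@dataclass
class FeatureMatrix:
    """Dense feature matrix (expression: genes x cell lines; fingerprints:
    drugs x bits)."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    kind: str = "expression"

    def __post_init__(self) -> None:
        self.row_ids = _check_unique(self.row_ids, "row")
        self.col_ids = _check_unique(self.col_ids, "column")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("feature matrix shape does not match labels")
        if not np.isfinite(self.values).all():
            raise ValueError(f"{self.kind} matrix contains missing/non-finite cells")
        if self.kind == "fingerprint":
            bad = ~np.isin(self.values, (0.0, 1.0))
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise ValueError(
                    f"fingerprint cell ({self.row_ids[r]!r}, {self.col_ids[c]!r}) "
                    f"is {self.values[r, c]!r}, not 0/1"
                )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)
        if self.kind == "fingerprint":
            df = df.astype(int)
        return df


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_labeled_matrix(path, kind: str):
    """Read a labeled matrix from delimited text (TSV/CSV by extension).

    First row = column labels, first column = row labels.  Empty cells,
    ``NA`` and ``NaN`` (case-insensitive) denote missing, accepted only for
    ``kind="response"``.  ``kind="similarity"`` additionally checks the
    matrix is square with matching labels and symmetric within 1e-8.
    """
    if kind not in {"response", "expression", "fingerprint", "similarity"}:
        raise ValueError(f"unknown matrix kind: {kind!r}")
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(sep)
    _check_unique(header[1:], "column")  # pandas silently mangles duplicates
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    row_ids = _check_unique(df.index, "row")
    col_ids = _check_unique(df.columns, "column")

    raw = df.to_numpy(dtype=str)
    stripped = np.char.strip(raw)
    missing = np.isin(np.char.lower(stripped), list(MISSING_TOKENS))
    # parse with numpy (correctly rounded) so 17-digit text round-trips exactly
    work = np.where(missing, "nan", stripped)
    bad = np.zeros(raw.shape, dtype=bool)
    try:
        numeric = work.astype(np.float64)
    except ValueError:
        numeric = np.full(raw.shape, np.nan)
        for idx in np.ndindex(raw.shape):
            try:
                numeric[idx] = float(work[idx])
            except ValueError:
                bad[idx] = True
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric cell at row {row_ids[r]!r}, column {col_ids[c]!r}: "
            f"{raw[r, c]!r}"
        )

    if kind == "response":
        return ResponseMatrix(row_ids, col_ids, numeric, ~missing)
    if missing.any():
        r, c = np.argwhere(missing)[0]
        raise ValueError(
            f"missing cell at row {row_ids[r]!r}, column {col_ids[c]!r} "
            f"not allowed in a {kind} matrix"
        )
    if kind == "similarity":
        from .similarity import SimilarityMatrix

        if row_ids != col_ids:
            raise ValueError("similarity matrix labels differ between rows and columns")
        if not np.allclose(numeric, numeric.T, atol=1e-8, rtol=0.0):
            raise ValueError("similarity matrix is not symmetric within 1e-8")
        return SimilarityMatrix(ids=row_ids, values=numeric, variant="COEF")
    return FeatureMatrix(row_ids, col_ids, numeric, kind=kind)


def write_labeled_matrix(obj, path) -> None:
    """Write a labeled matrix as delimited text with 17 significant digits,
    so a read round-trips float-exactly.  Unobserved entries become empty
    cells."""
    path = Path(path)
    df = obj.to_dataframe()
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g", na_rep="")


def align(
    response: ResponseMatrix, expr: FeatureMatrix, fp: FeatureMatrix
) -> tuple[ResponseMatrix, FeatureMatrix, FeatureMatrix]:
    """Restrict all three inputs to shared cell lines and drugs.

    Cell lines = response rows ∩ expression columns; drugs = response
    columns ∩ fingerprint rows; orders follow the response matrix.
    Idempotent; dropped labels are logged.
    """
    expr_cols = set(expr.col_ids)
    fp_rows = set(fp.row_ids)
    cells = [c for c in response.cell_line_ids if c in expr_cols]
    drugs = [d for d in response.drug_ids if d in fp_rows]
    if not cells or not drugs:
        raise ValueError("empty label intersection between response and feature matrices")

    dropped = (
        [c for c in response.cell_line_ids if c not in expr_cols]
        + [c for c in expr.col_ids if c not in cells]
        + [d for d in response.drug_ids if d not in fp_rows]
        + [d for d in fp.row_ids if d not in drugs]
    )
    if dropped:
        log.info("align: dropped %d unshared labels: %s", len(dropped), sorted(set(dropped)))

    ridx = [response.cell_line_ids.index(c) for c in cells]
    cidx = [response.drug_ids.index(d) for d in drugs]
    r2 = ResponseMatrix(
        cells, drugs, response.values[np.ix_(ridx, cidx)], response.observed[np.ix_(ridx, cidx)]
    )
    e2 = FeatureMatrix(
        list(expr.row_ids), cells,
        expr.values[:, [expr.col_ids.index(c) for c in cells]], kind=expr.kind,
    )
    f2 = FeatureMatrix(
        drugs, list(fp.col_ids),
        fp.values[[fp.row_ids.index(d) for d in drugs], :], kind=fp.kind,
    )
    return r2, e2, f2
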