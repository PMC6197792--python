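"""Cell-line and drug similarity under three definitions, with support shrinkage.

COEF is molecular-feature similarity: Pearson correlation of gene-expression
profiles for cell lines, Jaccard similarity of chemical-fingerprint bits
for drugs.  RPCC is the Pearson correlation of the two entities' response
profiles over their commonly observed entries, and MRPCC is the elementwise
product of the two.  Because response profiles overlap unevenly, similarities
used for neighbor ranking are shrunk by |U|/(|U| + alpha2), where |U| is the
number of commonly observed responses for the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import FeatureMatrix, ResponseMatrix

VARIANTS = ("COEF", "RPCC", "MRPCC")


@dataclass
class SimilarityMatrix:
    """Symmetric labeled similarity matrix with its variant tag and the
    pairwise support counts |U(i,j)| that drive shrinkage."""

    ids: list[str]
    values: np.ndarray
    variant: str
    support: np.ndarray | None = None
    shrunk: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.ids)
        if self.values.shape != (k, k):
            raise ValueError("similarity matrix must be square over its ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10, rtol=0.0):
            raise ValueError("similarity values are not symmetric within 1e-10")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown similarity variant: {self.variant!r}")
        if self.support is not None:
            self.support = np.asarray(self.support)
            if self.support.shape != (k, k):
                raise ValueError("support matrix shape mismatch")
            if (self.support < 0).any():
                raise ValueError("support counts must be nonnegative")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _corr_from_moments(n, sx, sy, sxx, syy, sxy):
    """Pearson correlation from pairwise sufficient statistics; undefined
    (zero variance or empty) maps to 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / np.maximum(n, 1)
        vx = sxx - sx**2 / np.maximum(n, 1)
        vy = syy - sy**2 / np.maximum(n, 1)
        denom = np.sqrt(vx * vy)
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.where(n >= 2, r, 0.0)
    return np.clip(r, -1.0, 1.0)


def pearson_similarity(X: FeatureMatrix) -> SimilarityMatrix:
    """COEF similarity: Pearson correlation between the columns of a
    feature matrix (entities in columns, e.g. cell lines over genes).

    Constant profiles have undefined correlation, recorded as 0.
    """
    V = X.values
    if V.shape[0] < 2:
        raise ValueError("pearson_similarity needs at least 2 feature rows")
    Vc = V - V.mean(axis=0, keepdims=True)
    sd = np.sqrt((Vc**2).sum(axis=0))
    ok = sd > 0
    Z = np.where(ok[None, :], Vc / np.where(ok, sd, 1.0)[None, :], 0.0)
    S = Z.T @ Z
    S[~ok, :] = 0.0
    S[:, ~ok] = 0.0
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, np.where(ok, 1.0, 0.0))
    return SimilarityMatrix(list(X.col_ids), S, "COEF")


def jaccard_similarity(F: FeatureMatrix) -> SimilarityMatrix:
    """COEF similarity for drugs: Jaccard score of fingerprint bit sets
    (drugs in rows).  Two all-zero fingerprints score 0 by convention."""
    B = F.values
    if not np.isin(B, (0.0, 1.0)).all():
        raise ValueError("fingerprint matrix must be binary")
    inter = B @ B.T
    pop = B.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return SimilarityMatrix(list(F.row_ids), S, "COEF")


def _pairwise_response_moments(Z: np.ndarray, M: np.ndarray):
    """Sufficient statistics over commonly observed rows for every column
    pair: Z is the matrix with unobserved entries zeroed, M the 0/1 mask."""
    n = M.T @ M
    sx = Z.T @ M          # sx[j,k] = sum over U(j,k) of z_vj
    sxx = (Z**2).T @ M
    sxy = Z.T @ Z
    return n, sx, sx.T, sxx, sxx.T, sxy


def response_pcc(R: ResponseMatrix, axis: str = "drugs", min_overlap: int = 3) -> SimilarityMatrix:
    """RPCC similarity: per-pair Pearson correlation of response profiles
    over commonly observed entries only.

    Pairs with overlap below ``min_overlap`` or zero variance on the overlap
    get similarity 0; the overlap count is recorded as support regardless.
    """
    if axis not in {"drugs", "cell_lines"}:
        raise ValueError(f"axis must be 'drugs' or 'cell_lines', got {axis!r}")
    if axis == "drugs":
        V, M = R.values, R.observed
        ids = list(R.drug_ids)
    else:
        V, M = R.values.T, R.observed.T
        ids = list(R.cell_line_ids)
    Mf = M.astype(float)
    Z = np.where(M, V, 0.0)
    n, sx, sy, sxx, syy, sxy = _pairwise_response_moments(Z, Mf)
    S = _corr_from_moments(n, sx, sy, sxx, syy, sxy)
    S = np.where(n >= max(min_overlap, 2), S, 0.0)
    S = (S + S.T) / 2.0
    support = np.rint(n).astype(int)
    return SimilarityMatrix(ids, S, "RPCC", support=support)


def combine_mrpcc(coef: SimilarityMatrix, rpcc: SimilarityMatrix) -> SimilarityMatrix:
    """MRPCC: elementwise product of feature similarity and response
    similarity; support carries over from the response side."""
    if coef.ids != rpcc.ids:
        raise ValueError("COEF and RPCC similarity matrices have mismatched ids")
    sup = rpcc.support.copy() if rpcc.support is not None else None
    return SimilarityMatrix(list(coef.ids), coef.values * rpcc.values, "MRPCC", support=sup)


def attach_support(S: SimilarityMatrix, R: ResponseMatrix, axis: str) -> SimilarityMatrix:
    """Attach response-overlap counts |U| to a feature-based similarity so it
    can be shrunk on the same footing as RPCC/MRPCC."""
    M = R.observed if axis == "drugs" else R.observed.T
    n = M.astype(float).T @ M.astype(float)
    return SimilarityMatrix(
        list(S.ids), S.values, S.variant, support=np.rint(n).astype(int), shrunk=S.shrunk
    )


def shrink_similarity(S: SimilarityMatrix, alpha2: float = 1.0) -> SimilarityMatrix:
    """Support shrinkage s' = s * |U|/(|U| + alpha2); the diagonal is left
    untouched.  Zero support zeroes the similarity; alpha2 = 0 is the
    identity transform."""
    if alpha2 < 0:
        raise ValueError("alpha2 must be >= 0")
    if S.support is None:
        raise ValueError("similarity matrix has no support counts to shrink with")
    sup = S.support.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(sup > 0, sup / (sup + alpha2), 0.0)
    out = S.values * factor
    np.fill_diagonal(out, np.diagonal(S.values))
    return SimilarityMatrix(list(S.ids), out, S.variant, support=S.support.copy(), shrunk=True)
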