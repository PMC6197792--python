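"""Neighborhood predictor: K nearest neighbors, shrunk normal equations,
non-negative interpolation weights.

A missing residual r_ui is predicted as a non-negative linear combination of
the target cell line's residuals on the K drugs most similar to drug i
(drug orientation), or of drug i's residuals on the K cell lines most
similar to cell line u (cell-line orientation); the hybrid variant averages
the two.  The weights solve the normal equations A w = b built from mean
co-products over commonly observed entries, with each entry shrunk toward
the average co-product by beta/(|U| + beta) because pair supports |U| can
differ by orders of magnitude on sparse response data.  The target cell
line (resp. drug) is excluded from every sum to avoid leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import nnls

from .global_effects import GlobalEffectsRemover
from .io_formats import ResponseMatrix
from .similarity import SimilarityMatrix

log = logging.getLogger("ncfger")

ORIENTATIONS = ("cell_line", "drug", "hybrid")


@dataclass(frozen=True)
class NeighborConfig:
    """Neighborhood hyperparameters: K neighbors, normal-equation shrinkage
    beta, orientation, and which similarity variant ranks neighbors."""

    k: int = 10
    beta: float = 500.0
    orientation: str = "hybrid"
    similarity_variant: str = "MRPCC"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")


@dataclass
class WeightSystem:
    """The shrunk normal equations for one prediction target."""

    A_bar: np.ndarray
    b_bar: np.ndarray
    A_hat: np.ndarray
    b_hat: np.ndarray
    avg: float
    supports: np.ndarray       # K x K pair-overlap counts |U(j,k)|
    b_supports: np.ndarray     # K-vector overlaps |U(i,j)| with the target


@dataclass
class NeighborPrediction:
    """A predicted entry with its neighbor sets, solved weights, and the
    residual-scale value before global effects are restored."""

    target: tuple[int, int]
    neighbors: dict
    weights: dict
    residual_value: float
    final_value: float
    fallback: bool = False

    @property
    def n_neighbors_cell(self) -> int:
        return len(self.neighbors.get("cell_line", ()))

    @property
    def n_neighbors_drug(self) -> int:
        return len(self.neighbors.get("drug", ()))


def select_neighbors(
    target: tuple[int, int],
    R_train: ResponseMatrix,
    S: SimilarityMatrix,
    k: int,
    orientation: str,
) -> list[int]:
    """Indices of the (at most) K candidates most similar to the target
    entity that have an observed training response at the counterpart index,
    in descending similarity; ties broken by ascending index."""
    u, i = target
    if orientation == "drug":
        observed_row = R_train.observed[u, :]
        cand = np.flatnonzero(observed_row)
        cand = cand[cand != i]
        sims = S.values[i, cand]
    elif orientation == "cell_line":
        observed_col = R_train.observed[:, i]
        cand = np.flatnonzero(observed_col)
        cand = cand[cand != u]
        sims = S.values[u, cand]
    else:
        raise ValueError("orientation must be 'drug' or 'cell_line' here")
    if cand.size == 0:
        return []
    order = np.lexsort((cand, -sims))
    return cand[order[:k]].tolist()


class _OrientationContext:
    """Precomputed cross-products over a training residual matrix, with the
    neighbor-supplying entities in columns, enabling O(K^2) system builds
    with the target row excluded by rank-one downdate."""

    def __init__(self, values: np.ndarray, observed: np.ndarray):
        self.M = observed.astype(float)
        self.Z = np.where(observed, values, 0.0)
        self.C = self.Z.T @ self.Z       # C[j,k] = sum over U(j,k) of r_vj r_vk
        self.N = self.M.T @ self.M       # N[j,k] = |U(j,k)|

    def system(self, u: int, i: int, neighbors, beta: float) -> WeightSystem:
        J = np.asarray(neighbors, dtype=int)
        zu, mu = self.Z[u, J], self.M[u, J]
        zui, mui = self.Z[u, i], self.M[u, i]

        Njk = self.N[np.ix_(J, J)] - np.outer(mu, mu)
        Cjk = self.C[np.ix_(J, J)] - np.outer(zu, zu)
        pos = Njk > 0
        A_bar = np.where(pos, Cjk / np.maximum(Njk, 1.0), 0.0)

        Nb = self.N[J, i] - mu * mui
        Cb = self.C[J, i] - zu * zui
        b_bar = np.where(Nb > 0, Cb / np.maximum(Nb, 1.0), 0.0)

        avg = float(A_bar[pos].mean()) if pos.any() else 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            A_hat = np.where(Njk + beta > 0, (Njk * A_bar + beta * avg) / np.maximum(Njk + beta, 1e-300), 0.0)
            b_hat = np.where(Nb + beta > 0, (Nb * b_bar + beta * avg) / np.maximum(Nb + beta, 1e-300), 0.0)
        return WeightSystem(
            A_bar=A_bar, b_bar=b_bar, A_hat=A_hat, b_hat=b_hat, avg=avg,
            supports=np.rint(Njk).astype(int), b_supports=np.rint(Nb).astype(int),
        )


def build_weight_system(
    target: tuple[int, int],
    neighbors,
    R_train: ResponseMatrix,
    beta: float,
    orientation: str = "drug",
) -> WeightSystem:
    """Build the shrunk normal equations for one target.

    Drug orientation: entries A_bar[j,k] average r_vj * r_vk over cell lines
    v (target cell line excluded) observed for both neighbor drugs; b_bar[j]
    averages r_vj * r_vi over the overlap with the target drug; both are
    shrunk toward the mean co-product ``avg`` by their supports.  Cell-line
    orientation is the exact transpose.
    """
    if len(neighbors) == 0:
        raise ValueError("cannot build a weight system with no neighbors")
    u, i = target
    if orientation == "drug":
        ctx = _OrientationContext(R_train.values, R_train.observed)
        return ctx.system(u, i, neighbors, beta)
    if orientation == "cell_line":
        ctx = _OrientationContext(R_train.values.T, R_train.observed.T)
        return ctx.system(i, u, neighbors, beta)
    raise ValueError("orientation must be 'drug' or 'cell_line'")


def solve_nonnegative_weights(system: WeightSystem, kkt_tol: float = 1e-8) -> np.ndarray:
    """Solve w = argmin_{w >= 0} w'Aw - 2 b'w for the shrunk system.

    A is symmetrised and eigendecomposed.  A need not be positive definite:
    support shrinkage toward a negative mean co-product can leave it
    indefinite or near-singular, in which case the raw program is ill-posed.
    Eigenvalues below ``1e-8 * lambda_max`` (including the entire negative
    spectrum) are therefore discarded (logged), and the program is solved on
    the retained spectrum as the non-negative least squares
    min ||diag(sqrt(lam)) V' w - diag(1/sqrt(lam)) V' b|| via Lawson-Hanson
    NNLS.  Well-conditioned positive-definite systems pass through exactly;
    the KKT conditions on the retained system are checked to ``kkt_tol``.
    """
    A = 0.5 * (system.A_hat + system.A_hat.T)
    b = np.asarray(system.b_hat, dtype=float)
    if not (np.isfinite(A).all() and np.isfinite(b).all()):
        raise ValueError("non-finite weight system")
    k = A.shape[0]
    if not A.any() and not b.any():
        return np.zeros(k)

    lam, V = np.linalg.eigh(A)
    keep = lam > 1e-8 * max(lam[-1], 0.0)
    if not keep.any():
        return np.zeros(k)
    if not keep.all():
        log.debug("dropped %d non-positive/near-null eigenvalues", int((~keep).sum()))
    lam_k, V_k = lam[keep], V[:, keep]
    root = np.sqrt(lam_k)
    F = root[:, None] * V_k.T              # F'F = retained A
    y = (V_k.T @ b) / root                 # F'y = projection of b
    w, _ = nnls(F, y)

    A_kept = (V_k * lam_k) @ V_k.T
    g = A_kept @ w - V_k @ (V_k.T @ b)
    scale = max(1.0, float(np.abs(A).max()), float(np.abs(b).max()))
    if (g < -kkt_tol * scale).any() or (np.abs(g[w > 0]) > kkt_tol * scale).any():
        raise RuntimeError("non-negative weight solve failed to satisfy KKT conditions")
    return w


class NeighborPredictor:
    """Bundles training residuals, the fitted effects model and the shrunk
    similarity pair; exposes entry-wise prediction for all orientations."""

    def __init__(
        self,
        R_train: ResponseMatrix,
        model: GlobalEffectsRemover | None,
        S_cell: SimilarityMatrix | None,
        S_drug: SimilarityMatrix | None,
        config: NeighborConfig,
    ):
        self.R_train = R_train
        self.model = model
        self.S_cell = S_cell
        self.S_drug = S_drug
        self.config = config
        self._ctx_drug = _OrientationContext(R_train.values, R_train.observed)
        self._ctx_cell = _OrientationContext(R_train.values.T, R_train.observed.T)

    def _one_orientation(self, u: int, i: int, orientation: str):
        if orientation == "drug":
            S, ctx, a, b = self.S_drug, self._ctx_drug, u, i
        else:
            S, ctx, a, b = self.S_cell, self._ctx_cell, i, u
        if S is None:
            return None, [], np.empty(0)
        neigh = select_neighbors((u, i), self.R_train, S, self.config.k, orientation)
        if not neigh:
            return None, [], np.empty(0)
        system = ctx.system(a, b, neigh, self.config.beta)
        w = solve_nonnegative_weights(system)
        if orientation == "drug":
            resid = float(w @ self.Z_row(u, neigh))
        else:
            resid = float(w @ self.Z_col(i, neigh))
        return resid, neigh, w

    def Z_row(self, u, J):
        return self._ctx_drug.Z[u, J]

    def Z_col(self, i, V):
        return self._ctx_cell.Z[i, V]

    def predict(self, u: int, i: int) -> NeighborPrediction:
        cfg = self.config
        neighbors: dict = {}
        weights: dict = {}
        parts = []
        orientations = (
            ("drug", "cell_line") if cfg.orientation == "hybrid" else (cfg.orientation,)
        )
        for orientation in orientations:
            resid, neigh, w = self._one_orientation(u, i, orientation)
            neighbors[orientation] = neigh
            weights[orientation] = w
            if resid is not None:
                parts.append(resid)
        fallback = not parts
        residual_value = float(np.mean(parts)) if parts else 0.0
        final = self.model.restore(u, i, residual_value) if self.model else residual_value
        return NeighborPrediction(
            target=(u, i), neighbors=neighbors, weights=weights,
            residual_value=residual_value, final_value=final, fallback=fallback,
        )


def predict_entry(
    target: tuple[int, int],
    R_train: ResponseMatrix,
    model: GlobalEffectsRemover | None,
    S_cell: SimilarityMatrix | None,
    S_drug: SimilarityMatrix | None,
    config: NeighborConfig,
) -> NeighborPrediction:
    """One-shot entry prediction (see :class:`NeighborPredictor`).

    R_train must already be on the residual scale of ``model``; the hybrid
    orientation averages the two residual-scale predictions, and entries
    with no usable neighbors fall back to the global-effects-only value.
    """
    predictor = NeighborPredictor(R_train, model, S_cell, S_drug, config)
    return predictor.predict(*target)
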