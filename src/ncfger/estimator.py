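"""Scikit-learn style imputer wrapping the full NCFGER pipeline.

fit() removes global effects from the observed entries, builds the chosen
similarity variant on the training data (never on held-out entries), and
precomputes the cross-products the neighborhood solver needs; predict()
then fills arbitrary entries and transform() completes the matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .global_effects import GlobalEffectsRemover
from .io_formats import FeatureMatrix, ResponseMatrix
from .neighbor_model import NeighborConfig, NeighborPredictor
from .similarity import (
    attach_support,
    combine_mrpcc,
    jaccard_similarity,
    pearson_similarity,
    response_pcc,
    shrink_similarity,
)

_ORIENTATIONS = ("cell_line", "drug", "hybrid", "baseline")


class NCFGERImputer(BaseEstimator):
    """Neighbor-based collaborative filtering with global-effect removal.

    Parameters
    ----------
    k : int, default=10
        Number of nearest neighbors per orientation.
    beta : float, default=500.0
        Shrinkage constant for the normal equations; entries supported by
        few co-observations are pulled toward the mean co-product.  The
        larger beta, the stronger the pull.
    alpha1_cell, alpha1_drug : float, default=3.0
        Shrinkage constants for the cell-line and drug main effects.
    alpha2 : float, default=1.0
        Support shrinkage constant for the similarity matrix used to rank
        neighbors.
    similarity : {"COEF", "RPCC", "MRPCC"}, default="MRPCC"
        COEF: expression correlation (cell lines) and fingerprint Jaccard
        (drugs); RPCC: response-profile correlation; MRPCC: their product.
    orientation : {"cell_line", "drug", "hybrid", "baseline"}, default="hybrid"
        Which entities supply neighbors; "hybrid" averages both predictions
        and "baseline" uses global effects only (no neighbors).
    min_overlap : int, default=3
        Minimum co-observation count for a response-correlation entry to be
        trusted (smaller overlaps are set to 0).
    rpcc_on : {"residuals", "raw"}, default="residuals"
        Whether response correlations are computed on post-removal residuals
        or on raw response values.

    Attributes
    ----------
    effects_ : GlobalEffectsRemover
        Fitted global-effects model.
    residuals_ : ResponseMatrix
        Training responses on the residual scale.
    sim_cell_, sim_drug_ : SimilarityMatrix or None
        Shrunk similarity matrices actually used for ranking.
    predictor_ : NeighborPredictor
        The entry-wise prediction engine.
    """

    def __init__(
        self,
        k: int = 10,
        beta: float = 500.0,
        alpha1_cell: float = 3.0,
        alpha1_drug: float = 3.0,
        alpha2: float = 1.0,
        similarity: str = "MRPCC",
        orientation: str = "hybrid",
        min_overlap: int = 3,
        rpcc_on: str = "residuals",
    ):
        self.k = k
        self.beta = beta
        self.alpha1_cell = alpha1_cell
        self.alpha1_drug = alpha1_drug
        self.alpha2 = alpha2
        self.similarity = similarity
        self.orientation = orientation
        self.min_overlap = min_overlap
        self.rpcc_on = rpcc_on

    # -- fitting -----------------------------------------------------------

    def _validate(self):
        if self.similarity not in ("COEF", "RPCC", "MRPCC"):
            raise ValueError(f"unknown similarity variant: {self.similarity!r}")
        if self.orientation not in _ORIENTATIONS:
            raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
        if self.rpcc_on not in ("residuals", "raw"):
            raise ValueError("rpcc_on must be 'residuals' or 'raw'")

    def _similarity_for(self, axis: str, R, R_resid, features):
        """Shrunk similarity for one entity axis ('cell_lines' or 'drugs')."""
        rpcc_base = R_resid if self.rpcc_on == "residuals" else R
        if self.similarity in ("RPCC", "MRPCC"):
            rpcc = response_pcc(rpcc_base, axis=axis, min_overlap=self.min_overlap)
        if self.similarity in ("COEF", "MRPCC"):
            if features is None:
                kind = "expression" if axis == "cell_lines" else "fingerprint"
                raise ValueError(
                    f"similarity={self.similarity!r} needs a {kind} matrix at fit time"
                )
            coef = pearson_similarity(features) if axis == "cell_lines" else jaccard_similarity(features)
        if self.similarity == "RPCC":
            S = rpcc
        elif self.similarity == "COEF":
            S = attach_support(coef, R_resid, axis)
        else:
            S = combine_mrpcc(coef, rpcc)
        return shrink_similarity(S, self.alpha2)

    def fit(self, X, y=None, expression=None, fingerprints=None):
        """Fit on a training response matrix.

        Parameters
        ----------
        X : ResponseMatrix or array of shape (m, n)
            Training responses; NaN marks unobserved entries when an array
            is passed.
        expression : FeatureMatrix or array (n_genes, m), optional
            Gene-expression profiles, cell lines in columns (COEF/MRPCC).
        fingerprints : FeatureMatrix or array (n, n_bits), optional
            Binary chemical fingerprints, drugs in rows (COEF/MRPCC).
        """
        self._validate()
        R = X if isinstance(X, ResponseMatrix) else ResponseMatrix.from_array(X)
        expr = _as_feature(expression, "expression")
        fp = _as_feature(fingerprints, "fingerprint")
        if expr is not None and len(expr.col_ids) != R.m:
            raise ValueError("expression columns do not match response cell lines")
        if fp is not None and len(fp.row_ids) != R.n:
            raise ValueError("fingerprint rows do not match response drugs")

        self.effects_ = GlobalEffectsRemover(
            alpha_cell=self.alpha1_cell, alpha_drug=self.alpha1_drug
        ).fit(R)
        self.residuals_ = ResponseMatrix(
            list(R.cell_line_ids), list(R.drug_ids),
            self.effects_.residuals_, R.observed.copy(),
        )

        need_cell = self.orientation in ("cell_line", "hybrid")
        need_drug = self.orientation in ("drug", "hybrid")
        self.sim_cell_ = (
            self._similarity_for("cell_lines", R, self.residuals_, expr) if need_cell else None
        )
        self.sim_drug_ = (
            self._similarity_for("drugs", R, self.residuals_, fp) if need_drug else None
        )

        cfg_orientation = "hybrid" if self.orientation == "baseline" else self.orientation
        self.config_ = NeighborConfig(
            k=self.k, beta=self.beta, orientation=cfg_orientation,
            similarity_variant=self.similarity,
        )
        self.predictor_ = NeighborPredictor(
            self.residuals_, self.effects_, self.sim_cell_, self.sim_drug_, self.config_
        )
        self.n_features_in_ = R.n
        return self

    # -- prediction --------------------------------------------------------

    def predict_entries(self, entries):
        """Detailed predictions for an iterable of (cell_line, drug) index
        pairs; returns a list of NeighborPrediction."""
        if not hasattr(self, "predictor_"):
            raise RuntimeError("imputer is not fitted")
        return [self.predictor_.predict(int(u), int(i)) for u, i in entries]

    def predict(self, entries) -> np.ndarray:
        """Predicted response values (effects restored) for (u, i) pairs."""
        return np.array([p.final_value for p in self.predict_entries(entries)])

    def transform(self, X=None) -> np.ndarray:
        """Complete the fitted matrix: observed entries kept, unobserved
        entries imputed.  X defaults to the training matrix."""
        if X is None:
            R = self.residuals_
            values = self.effects_.inverse_transform(np.where(R.observed, R.values, np.nan))
            observed = R.observed
        else:
            R = X if isinstance(X, ResponseMatrix) else ResponseMatrix.from_array(X)
            values, observed = R.values, R.observed
        out = np.array(values, dtype=float)
        missing = np.argwhere(~observed)
        if missing.size:
            out[~observed] = self.predict(missing)
        return out


def _as_feature(obj, kind):
    if obj is None or isinstance(obj, FeatureMatrix):
        return obj
    arr = np.asarray(obj, dtype=float)
    return FeatureMatrix(
        [f"r{j}" for j in range(arr.shape[0])],
        [f"c{j}" for j in range(arr.shape[1])],
        arr,
        kind=kind,
    )
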