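"""Sequential estimation and removal of global effects with Bayesian shrinkage.

Drug-response matrices carry strong additive structure: an overall level,
systematically sensitive or resistant cell lines, and systematically potent
or weak drugs.  Each effect is estimated in turn on the residuals of the
previous step under the one-parameter model r = theta * x + eps, with the
per-entity least-squares estimate shrunk toward zero by n/(n + alpha1) so
that entities supported by few responses contribute little.  The fitted
model is invertible: removal followed by restoration reproduces the
observed values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io_formats import ResponseMatrix

#: Default effect chain: overall mean (unshrunk), then per-cell-line and
#: per-drug offsets, both with alpha1 = 3.
DEFAULT_ALPHA1 = 3.0


@dataclass(frozen=True)
class EffectSpec:
    """One additive effect: its name, the axis it varies over, and its
    shrinkage constant alpha (dimensionless, >= 0)."""

    name: str  # overall_mean | cell_line_main | drug_main
    axis: str  # scalar | row | column
    alpha: float

    _AXES = {"overall_mean": "scalar", "cell_line_main": "row", "drug_main": "column"}

    def __post_init__(self) -> None:
        if self.name not in self._AXES:
            raise ValueError(f"unknown effect name: {self.name!r}")
        if self.axis != self._AXES[self.name]:
            raise ValueError(f"effect {self.name!r} must have axis {self._AXES[self.name]!r}")
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError("alpha must be finite and >= 0")


def default_specs(alpha_cell: float = DEFAULT_ALPHA1, alpha_drug: float = DEFAULT_ALPHA1):
    """The standard three-effect chain, in removal order."""
    return [
        EffectSpec("overall_mean", "scalar", 0.0),
        EffectSpec("cell_line_main", "row", alpha_cell),
        EffectSpec("drug_main", "column", alpha_drug),
    ]


def estimate_effect(residuals, x, alpha: float) -> float:
    """Shrunk one-entity effect estimate.

    theta_hat = (sum r*x / sum x^2) * n/(n + alpha); an entity with no
    observations or a degenerate explanatory variable (sum x^2 == 0) gets 0.
    """
    r = np.asarray(residuals, dtype=float)
    x = np.asarray(x, dtype=float)
    if not np.isfinite(r).all():
        raise ValueError("non-finite residual passed to estimate_effect")
    n = r.size
    if n == 0:
        return 0.0
    sxx = float(x @ x)
    if sxx == 0.0:
        return 0.0
    theta = float(r @ x) / sxx
    return theta * n / (n + alpha)


def _estimate_along(values: np.ndarray, observed: np.ndarray, spec: EffectSpec) -> np.ndarray:
    """Vectorised per-entity estimates for an x==1 effect along one axis."""
    z = np.where(observed, values, 0.0)
    if spec.axis == "scalar":
        n = observed.sum()
        theta = np.array([z.sum() / n if n else 0.0])
        return theta * (n / (n + spec.alpha) if n else 0.0)
    ax = 1 if spec.axis == "row" else 0
    n = observed.sum(axis=ax).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(n > 0, z.sum(axis=ax) / np.maximum(n, 1), 0.0)
    return theta * n / (n + spec.alpha)


def _broadcast(theta: np.ndarray, spec: EffectSpec, shape) -> np.ndarray:
    if spec.axis == "scalar":
        return np.full(shape, theta[0])
    if spec.axis == "row":
        return np.broadcast_to(theta[:, None], shape)
    return np.broadcast_to(theta[None, :], shape)


class GlobalEffectsRemover(BaseEstimator, TransformerMixin):
    """Transformer removing additive global effects from observed responses.

    Parameters
    ----------
    alpha_cell, alpha_drug : float
        Shrinkage constants for the cell-line and drug main effects.  The
        overall mean is never shrunk.
    specs : list of EffectSpec, optional
        Explicit effect chain overriding the two alphas; applied in order.

    Attributes
    ----------
    effects_ : list of (EffectSpec, ndarray)
        Fitted per-entity estimates, in removal order.
    fit_mask_ : ndarray of bool
        Observed mask the model was fitted on.
    """

    def __init__(self, alpha_cell: float = DEFAULT_ALPHA1,
                 alpha_drug: float = DEFAULT_ALPHA1, specs=None):
        self.alpha_cell = alpha_cell
        self.alpha_drug = alpha_drug
        self.specs = specs

    def _resolved_specs(self):
        if self.specs is not None:
            return list(self.specs)
        return default_specs(self.alpha_cell, self.alpha_drug)

    def fit(self, X, y=None):
        values, observed = _as_values_mask(X)
        if observed.sum() < 1:
            raise ValueError("need at least one observed entry to fit global effects")
        resid = np.where(observed, values, np.nan)
        effects = []
        for spec in self._resolved_specs():
            theta = _estimate_along(resid, observed, spec)
            resid = resid - _broadcast(theta, spec, resid.shape)
            effects.append((spec, theta))
        self.effects_ = effects
        self.fit_mask_ = observed.copy()
        self.residuals_ = np.where(observed, resid, np.nan)
        return self

    def transform(self, X):
        """Return residual values (NaN at unobserved entries)."""
        values, observed = _as_values_mask(X)
        return np.where(observed, values - self.effect_surface(values.shape), np.nan)

    def inverse_transform(self, X):
        values = np.asarray(X, dtype=float)
        return values + self.effect_surface(values.shape)

    def effect_surface(self, shape) -> np.ndarray:
        """Total fitted effect theta-contribution for every (u, i)."""
        total = np.zeros(shape)
        for spec, theta in self.effects_:
            total += _broadcast(theta, spec, shape)
        return total

    def restore(self, u: int, i: int, residual_prediction: float) -> float:
        """Add the fitted effects for entry (u, i) back onto a residual-scale
        prediction (reverse removal order; addition commutes)."""
        total = float(residual_prediction)
        m, n = self.fit_mask_.shape
        if not (0 <= u < m and 0 <= i < n):
            raise IndexError(f"entry ({u}, {i}) outside fitted {m}x{n} matrix")
        for spec, theta in reversed(self.effects_):
            if spec.axis == "scalar":
                total += theta[0]
            elif spec.axis == "row":
                total += theta[u]
            else:
                total += theta[i]
        return total


def _as_values_mask(X):
    if isinstance(X, ResponseMatrix):
        return X.values, X.observed
    values = np.asarray(X, dtype=float)
    return values, ~np.isnan(values)


def fit_remove(R: ResponseMatrix, specs=None) -> tuple[GlobalEffectsRemover, ResponseMatrix]:
    """Fit the effect chain on R and return (model, residual matrix).

    An empty spec list yields an identity model (residuals == values).
    """
    model = GlobalEffectsRemover(specs=specs).fit(R)
    resid = ResponseMatrix(
        list(R.cell_line_ids), list(R.drug_ids), model.residuals_, R.observed.copy()
    )
    return model, resid


def restore(model: GlobalEffectsRemover, u: int, i: int, residual_prediction: float) -> float:
    return model.restore(u, i, residual_prediction)
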