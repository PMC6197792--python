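"""Synthetic fixture generator with the structure the predictor assumes.

Responses are additive global effects plus a low-rank cell-line x drug
interaction plus i.i.d. Gaussian noise:

    r_ui = mu + a_u + b_i + sum_f lambda_f p_uf q_if + eps_ui

Expression profiles are noisy linear read-outs of a *distorted* copy of the
cell-line factors p, so expression correlation tracks latent cell-line
similarity without being an oracle for it: in real panels molecular
similarity is an imperfect proxy for response-relevant similarity (which is
why response-derived similarity carries extra information).  Fingerprint
bits are likewise random halfspace indicators of distorted drug factors q.
Masking is missing-at-random at a configurable rate, with a guard against
fully missing rows/columns.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np

from .io_formats import FeatureMatrix, ResponseMatrix

log = logging.getLogger("ncfger")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings.

    Response scale loosely follows log-IC50 panels: overall mean near 2,
    drug offsets wider than cell-line offsets, a rank-3 interaction of
    magnitude comparable to the main effects, and measurement noise well
    below the signal.
    """

    m: int = 100
    n: int = 30
    rank: int = 3
    mu: float = 2.0
    sigma_row: float = 0.5
    sigma_col: float = 1.0
    sigma_noise: float = 0.3
    missing_rate: float = 0.3
    lambda_scale: float = 0.5
    n_genes: int = 500
    sigma_expr: float = 1.0
    sigma_proxy: float = 0.5
    n_bits: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_row", "sigma_col", "sigma_noise", "lambda_scale",
                     "sigma_expr", "sigma_proxy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.rank > min(self.m, self.n):
            raise ValueError("rank cannot exceed min(m, n)")
        if self.rank < 0 or self.m < 1 or self.n < 1:
            raise ValueError("invalid dimensions")


def _guarded_mask(rng, m, n, missing_rate) -> np.ndarray:
    """i.i.d. Bernoulli observed-mask, rescuing all-missing rows/columns by
    re-observing a random entry (logged)."""
    observed = rng.random((m, n)) >= missing_rate
    rescued = 0
    for u in np.flatnonzero(~observed.any(axis=1)):
        observed[u, rng.integers(n)] = True
        rescued += 1
    for i in np.flatnonzero(~observed.any(axis=0)):
        observed[rng.integers(m), i] = True
        rescued += 1
    if rescued:
        log.info("mask guard re-observed %d entries to avoid empty rows/columns", rescued)
    return observed


def generate(spec: SyntheticSpec):
    """Generate (response, expression, fingerprints, truth) for a spec.

    Fully deterministic given ``spec.seed``.  ``truth`` carries the latent
    parameters (mu, a, b, P, Q, lam) and the complete noiseless-mask
    response matrix ``R_full`` for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    a = rng.normal(0.0, spec.sigma_row, spec.m)
    b = rng.normal(0.0, spec.sigma_col, spec.n)
    P = rng.normal(0.0, 1.0, (spec.m, spec.rank))
    Q = rng.normal(0.0, 1.0, (spec.n, spec.rank))
    lam = np.full(spec.rank, spec.lambda_scale)
    interaction = (P * lam) @ Q.T if spec.rank else np.zeros((spec.m, spec.n))
    noise = rng.normal(0.0, spec.sigma_noise, (spec.m, spec.n))
    R_full = spec.mu + a[:, None] + b[None, :] + interaction + noise

    observed = _guarded_mask(rng, spec.m, spec.n, spec.missing_rate)
    cell_ids = [f"CL{u:03d}" for u in range(spec.m)]
    drug_ids = [f"D{i:03d}" for i in range(spec.n)]
    response = ResponseMatrix(
        cell_ids, drug_ids, np.where(observed, R_full, np.nan), observed
    )

    P_proxy = P + rng.normal(0.0, spec.sigma_proxy, P.shape)
    Q_proxy = Q + rng.normal(0.0, spec.sigma_proxy, Q.shape)
    loadings = rng.normal(0.0, 1.0, (spec.n_genes, spec.rank))
    expr = loadings @ P_proxy.T + rng.normal(0.0, spec.sigma_expr, (spec.n_genes, spec.m))
    expression = FeatureMatrix(
        [f"G{g:04d}" for g in range(spec.n_genes)], cell_ids, expr, kind="expression"
    )

    directions = rng.normal(0.0, 1.0, (spec.n_bits, max(spec.rank, 1)))
    proj = Q_proxy @ directions.T if spec.rank else np.zeros((spec.n, spec.n_bits))
    bits = (proj + rng.normal(0.0, 1.0, (spec.n, spec.n_bits)) > 0).astype(float)
    fingerprints = FeatureMatrix(
        drug_ids, [f"B{t:03d}" for t in range(spec.n_bits)], bits, kind="fingerprint"
    )

    truth = {
        "spec": asdict(spec),
        "mu": spec.mu,
        "a": a,
        "b": b,
        "P": P,
        "Q": Q,
        "lam": lam,
        "R_full": R_full,
        "observed": observed,
    }
    return response, expression, fingerprints, truth
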