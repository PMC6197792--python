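"""Repeated entry-wise 10-fold cross-validation and per-drug metrics.

Observed response entries are partitioned at random into folds of nearly
equal size; each fold in turn is hidden, the model is refit on the rest
(global effects, similarities and weight systems all see only training
entries), and the hidden entries are predicted.  Per drug we report PCC and
RMSE over the pooled test entries of a repetition, plus PCC_S/R and
RMSE_S/R restricted to that drug's sensitive (first quartile) and resistant
(fourth quartile) cell lines; drug-averaged values are unweighted means
over eligible drugs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimator import NCFGERImputer
from .io_formats import ResponseMatrix

log = logging.getLogger("ncfger")

METRICS = ("pcc", "rmse", "pcc_sr", "rmse_sr")


def make_folds(observed_entries, n_folds: int, seed) -> list[np.ndarray]:
    """Random partition of entry indices into ``n_folds`` disjoint folds
    whose sizes differ by at most one; deterministic given the seed (an int
    or a numpy Generator)."""
    entries = np.asarray(observed_entries)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if len(entries) < n_folds:
        raise ValueError(f"{len(entries)} entries cannot fill {n_folds} folds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(entries))
    return [entries[idx] for idx in np.array_split(perm, n_folds)]


def sr_labels(observed_drug_responses) -> np.ndarray:
    """Quartile sensitive/resistant labels for one drug's observed responses.

    Values at or below the first quartile are 'sensitive', at or above the
    third quartile 'resistant', the rest 'neither'; quartiles use linear
    interpolation.  Fewer than 4 responses, or values qualifying for both
    extremes (degenerate spread), are labeled 'neither'.
    """
    v = np.asarray(observed_drug_responses, dtype=float)
    labels = np.full(v.shape, "neither", dtype=object)
    if v.size < 4:
        return labels
    q1, q3 = np.quantile(v, [0.25, 0.75])
    sens = v <= q1
    res = v >= q3
    both = sens & res
    labels[sens & ~both] = "sensitive"
    labels[res & ~both] = "resistant"
    return labels


def _pcc(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2:
        return np.nan
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero-variance vector in PCC; recording 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class CVReport:
    """Cross-validation results: one row per (repetition, drug), plus
    drug-averaged summaries with spreads across drugs and across repeats."""

    per_drug: pd.DataFrame
    drug_averaged: dict
    repeats: int
    seed: int
    config: dict = field(default_factory=dict)
    excluded_drugs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "repeats": self.repeats,
            "seed": self.seed,
            "per_drug": self.per_drug.to_dict(orient="records"),
            "drug_averaged": self.drug_averaged,
            "excluded_drugs": self.excluded_drugs,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


def score(predictions, truths, entries, drug_ids, labels_by_drug) -> pd.DataFrame:
    """Per-drug metrics for one repetition's pooled test predictions.

    ``entries`` are (cell_line, drug) index pairs aligned with
    ``predictions``/``truths``; ``labels_by_drug`` maps drug index ->
    per-cell-line S/R label array (length m).
    """
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    entries = np.asarray(entries)
    rows = []
    for i in np.unique(entries[:, 1]):
        sel = entries[:, 1] == i
        yp, yt = predictions[sel], truths[sel]
        cells = entries[sel, 0]
        lab = labels_by_drug[int(i)][cells]
        in_sr = lab != "neither"
        rows.append(
            {
                "drug": drug_ids[int(i)] if drug_ids is not None else int(i),
                "drug_index": int(i),
                "n_test": int(sel.sum()),
                "pcc": _pcc(yt, yp),
                "rmse": _rmse(yt, yp),
                "n_sr": int(in_sr.sum()),
                "pcc_sr": _pcc(yt[in_sr], yp[in_sr]),
                "rmse_sr": _rmse(yt[in_sr], yp[in_sr]) if in_sr.sum() >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _drug_averages(per_drug: pd.DataFrame) -> dict:
    """Unweighted means over eligible drugs, per repetition, then summarised
    across repetitions (mean, s.d. across repeats) and across drugs."""
    eligible = per_drug[per_drug["n_test"] >= 2]
    out: dict = {}
    rep_means = eligible.groupby("repeat")[list(METRICS)].mean()
    for metric in METRICS:
        out[metric] = float(rep_means[metric].mean())
        out[f"sd_{metric}_across_repeats"] = float(rep_means[metric].std(ddof=1)) if len(rep_means) > 1 else 0.0
        by_drug = eligible.groupby("drug_index")[metric].mean()
        out[f"sd_{metric}_across_drugs"] = float(by_drug.std(ddof=1)) if len(by_drug) > 1 else 0.0
    return out


def cross_validate(
    R: ResponseMatrix,
    expression=None,
    fingerprints=None,
    *,
    params: dict | None = None,
    n_folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
) -> CVReport:
    """Repeated entry-wise k-fold cross-validation of the imputer.

    Every observed entry is hidden exactly once per repetition.  S/R labels
    are fixed from each drug's full observed response distribution.
    """
    params = dict(params or {})
    entries = np.argwhere(R.observed)
    labels_by_drug = {}
    for i in range(R.n):
        lab = np.full(R.m, "neither", dtype=object)
        obs = R.observed[:, i]
        lab[obs] = sr_labels(R.values[obs, i])
        labels_by_drug[i] = lab

    rng = np.random.default_rng(seed)
    frames = []
    for rep in range(repeats):
        preds = np.full(R.observed.shape, np.nan)
        for fold in make_folds(entries, n_folds, rng):
            R_train = R.mask_entries(fold)
            imputer = NCFGERImputer(**params)
            imputer.fit(R_train, expression=expression, fingerprints=fingerprints)
            preds[fold[:, 0], fold[:, 1]] = imputer.predict(fold)
        pd_rep = score(
            preds[entries[:, 0], entries[:, 1]],
            R.values[entries[:, 0], entries[:, 1]],
            entries,
            R.drug_ids,
            labels_by_drug,
        )
        pd_rep.insert(0, "repeat", rep)
        frames.append(pd_rep)
        log.info("cv repeat %d/%d done", rep + 1, repeats)

    per_drug = pd.concat(frames, ignore_index=True)
    excluded = (
        per_drug.groupby("drug")["n_test"].sum()[lambda s: s < 2].index.tolist()
    )
    return CVReport(
        per_drug=per_drug,
        drug_averaged=_drug_averages(per_drug),
        repeats=repeats,
        seed=seed,
        config={"n_folds": n_folds, "repeats": repeats, "seed": seed, **params},
        excluded_drugs=excluded,
    )
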