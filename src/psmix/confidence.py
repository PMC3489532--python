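"""Confidence measures derived from a fitted score mixture.

Four measures, all per charge:

* PEP (posterior error probability, a.k.a. local FDR):
  P(incorrect | score) from the Bayes posterior of the fitted mixture.
* p-value / FPR: the negative component's upper tail P(S > s | incorrect);
  the two are the same tail read at a point vs a cutoff.
* FDR at cutoff t, three estimators:
  - model-based:   pi0 A0 / (pi0 A0 + (1-pi0) A1), A_c = P(S > t | T=c),
    optionally conditioned on discrete feature levels (each tail picks up
    its component's probability of the conditioned level);
  - mean-PEP:      average PEP of records with score >= t;
  - decoy-ratio:   #decoys above t / #targets above t.
* q-value: the minimum FDR over all cutoffs at or below the score —
  the monotone envelope of the (not necessarily monotone) FDR curve.

Tail comparisons use strict ``> t``; the mean-PEP set uses ``>= t``,
matching how each formula is stated. At a tied cutoff the two may differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from psmix.psm_data import PSMTable
from psmix.mixture import (
    FitResult,
    MixtureError,
    MixtureModel,
    component_tail,
    e_step,
)

__all__ = [
    "ConfidenceTable",
    "pep_at",
    "p_value_at",
    "fpr_at",
    "fdr_model",
    "fdr_mean_pep",
    "fdr_decoy_ratio",
    "q_values",
    "build_confidence_table",
]


@dataclass
class ConfidenceTable:
    """Per-record confidence measures plus method metadata."""

    spectrum_ids: list[str]
    charges: np.ndarray
    scores: np.ndarray
    pep: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    is_decoy: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spectrum_id": self.spectrum_ids,
                "charge": self.charges,
                "score": self.scores,
                "pep": self.pep,
                "p_value": self.p_value,
                "q_value": self.q_value,
                "is_decoy": self.is_decoy,
            }
        )

    def write(self, path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=False, float_format="%.10g")


def pep_at(model: MixtureModel, s: float, discrete_levels: dict | None = None) -> float:
    """Posterior error probability at score ``s`` (delegates to the E-step)."""
    return e_step(model, s, discrete_levels)


def p_value_at(model: MixtureModel, s) -> float | np.ndarray:
    """P(S > s | incorrect): the negative component's upper tail."""
    return component_tail(model.negative, s)


def fpr_at(model: MixtureModel, t) -> float | np.ndarray:
    """False positive rate at cutoff ``t``; identical to the p-value tail."""
    return p_value_at(model, t)


def fdr_model(
    model: MixtureModel,
    t: float,
    discrete_condition: Mapping[str, object] | None = None,
) -> float:
    """Model-based FDR at cutoff ``t``.

    pi0*A0 / (pi0*A0 + (1-pi0)*A1) with A_c = P(S > t | T=c). A discrete
    condition (e.g. ``{"nmc": 0}``) multiplies each component tail by that
    component's probability of the conditioned level, restricting the FDR
    to records with those feature values.
    """
    a0 = float(component_tail(model.negative, t))
    a1 = float(component_tail(model.positive, t))
    if discrete_condition:
        for feature, level in discrete_condition.items():
            table = next(
                (tab for tab in model.discrete_features if tab.feature == feature), None
            )
            if table is None:
                raise MixtureError(f"model has no fitted discrete table for {feature!r}")
            a0 *= table.prob(level, 0)
            a1 *= table.prob(level, 1)
    num = model.pi0 * a0
    den = num + (1.0 - model.pi0) * a1
    if den == 0.0:
        raise MixtureError(f"empty rejection region above t={t}")
    return num / den


def fdr_mean_pep(peps: Sequence[float], scores: Sequence[float], t: float) -> float:
    """Mean-PEP FDR at cutoff ``t``: average PEP over records with score >= t."""
    peps = np.asarray(peps, dtype=float)
    scores = np.asarray(scores, dtype=float)
    mask = scores >= t
    if not mask.any():
        raise MixtureError(f"no records with score >= {t}")
    return float(peps[mask].mean())


def fdr_decoy_ratio(table: PSMTable, t: float) -> float:
    """Decoy-ratio FDR at cutoff ``t``: #decoys above t / #targets above t."""
    scores = np.array(
        [r.discriminant_score for r in table.records if r.discriminant_score is not None]
    )
    decoy = np.array(
        [r.is_decoy for r in table.records if r.discriminant_score is not None], dtype=bool
    )
    if not decoy.any() or decoy.all():
        raise MixtureError("decoy-ratio FDR needs both decoys and targets")
    n_decoys = int(((scores > t) & decoy).sum())
    n_targets = int(((scores > t) & ~decoy).sum())
    if n_targets == 0:
        raise MixtureError(f"no target records above t={t}")
    return n_decoys / n_targets


def q_values(scores: Sequence[float], fdr_at: Callable[[float], float]) -> np.ndarray:
    """q-value per score: the minimum FDR over observed cutoffs <= the score.

    Evaluates ``fdr_at`` once per distinct observed score and takes the
    running minimum from the lowest cutoff upward; output is aligned to
    the input order.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise MixtureError("q_values requires at least one score")
    uniq = np.unique(scores)
    fdrs = np.array([fdr_at(c) for c in uniq])
    cummin = np.minimum.accumulate(fdrs)
    idx = np.searchsorted(uniq, scores)
    return cummin[idx]


def q_values_grid(
    lo: float, hi: float, step: float, fdr_at: Callable[[float], float]
) -> Callable[[float], float]:
    """Grid-mode q-values: cumulative-min FDR over a dense cutoff grid.

    Returns an accessor q(s) = min FDR over grid cutoffs <= s. Matches the
    style of scanning cutoffs at fixed increments rather than at observed
    scores only.
    """
    grid = np.arange(lo, hi + step / 2, step)
    fdrs = np.array([fdr_at(c) for c in grid])
    cummin = np.minimum.accumulate(fdrs)

    def q(s: float) -> float:
        idx = int(np.searchsorted(grid, s, side="right")) - 1
        if idx < 0:
            raise MixtureError(f"score {s} below the grid start {lo}")
        return float(cummin[idx])

    return q


def build_confidence_table(
    fit: FitResult,
    table: PSMTable,
    fdr_method: str = "model",
) -> ConfidenceTable:
    """Assemble per-record PEP, p-value and q-value from a fit.

    q-values are computed per charge from the chosen FDR estimator
    evaluated at every observed score of that charge. ``fdr_method`` is
    ``"model"`` (mixture tails) or ``"mean_pep"`` (average of local FDRs).
    """
    if fdr_method not in ("model", "mean_pep"):
        raise ValueError(f"unknown fdr_method {fdr_method!r}")
    idx_records = [
        (i, rec)
        for i, rec in enumerate(table.records)
        if rec.discriminant_score is not None and rec.charge in fit.models
    ]
    missing = {
        rec.charge
        for rec in table.records
        if rec.discriminant_score is not None
        and rec.charge not in fit.models
        and rec.charge not in fit.skipped_charges
    }
    if missing:
        raise MixtureError(f"fit has no model for charges {sorted(missing)}")

    n = len(idx_records)
    scores = np.array([rec.discriminant_score for _, rec in idx_records])
    charges = np.array([rec.charge for _, rec in idx_records])
    pep = np.array([fit.pep[i] for i, _ in idx_records])
    p_value = np.empty(n)
    q_value = np.empty(n)
    for charge, model in fit.models.items():
        mask = charges == charge
        p_value[mask] = np.asarray(component_tail(model.negative, scores[mask]))
        if fdr_method == "model":
            accessor = lambda t, m=model: fdr_model(m, t)  # noqa: E731
        else:
            c_pep, c_scores = pep[mask], scores[mask]
            accessor = lambda t, p=c_pep, s=c_scores: fdr_mean_pep(p, s, t)  # noqa: E731
        q_value[mask] = q_values(scores[mask], accessor)

    return ConfidenceTable(
        spectrum_ids=[rec.spectrum_id for _, rec in idx_records],
        charges=charges,
        scores=scores,
        pep=pep,
        p_value=p_value,
        q_value=np.clip(q_value, 0.0, 1.0),
        is_decoy=np.array([rec.is_decoy for _, rec in idx_records], dtype=bool),
        metadata={"fdr_method": fdr_method},
    )
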