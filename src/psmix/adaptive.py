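"""Adaptive re-estimation of discriminant coefficients.

Fixed discriminant coefficients are trained on unconstrained searches;
in a constrained search (small database, narrow mass tolerance) they can
separate correct from incorrect matches poorly. The adaptive scheme
re-learns the coefficients from the experiment itself:

1. score the current best candidate of every spectrum;
2. fit the score mixture and compute PEPs;
3. take confident incorrect matches (PEP >= pep_high) as negatives and
   confident correct ones (PEP <= pep_low) as positives;
4. draw I random subsamples of the positives, train a Fisher linear
   discriminant per subsample against the full negative set, and average
   the I coefficient vectors;
5. rescore the top-K candidates of every spectrum with the averaged
   coefficients and promote each spectrum's highest-scoring candidate;
6. repeat until the coefficients move by less than epsilon.

Step 5 lets a lower-ranked candidate overtake the search engine's
original rank-1 match under the improved score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from psmix.psm_data import PSMRecord, PSMTable
from psmix.discriminant import DiscriminantCoefficients, score_record
from psmix.mixture import FitOptions, FitResult, MixtureError, fit_em

__all__ = [
    "CandidateSet",
    "AdaptiveOptions",
    "train_linear_discriminant",
    "select_best_candidates",
    "fit_adaptive",
]


@dataclass
class CandidateSet:
    """Top-K candidate matches of one spectrum, ranks strictly increasing from 1."""

    spectrum_id: str
    candidates: list[PSMRecord]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("candidate set must be non-empty")
        ranks = [c.rank for c in self.candidates]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(f"ranks must be 1..K strictly increasing, got {ranks}")
        if any(c.spectrum_id != self.spectrum_id for c in self.candidates):
            raise ValueError("all candidates must share the set's spectrum_id")


@dataclass
class AdaptiveOptions:
    """Tuning knobs of the adaptive loop."""

    pep_low: float = 0.05  # PEP at or below which a record joins the positive training set
    pep_high: float = 0.9  # PEP at or above which a record joins the negative training set
    # floor on each training set: when the PEP thresholds select fewer
    # records (heavy component overlap early in the loop), the selection is
    # padded with the most confident records by PEP rank — a handful of
    # training points makes the discriminant oscillate round to round
    min_training: int = 50
    n_resample: int = 10  # number I of positive-set subsamples / discriminants averaged
    subsample_fraction: float = 0.7
    epsilon: float = 1e-4
    max_rounds: int = 20
    top_k: int = 5
    ridge: float = 1e-6
    seed: int = 0
    fit_options: FitOptions = field(default_factory=FitOptions)

    def __post_init__(self) -> None:
        if not self.pep_low < self.pep_high:
            raise ValueError("pep_low must be < pep_high")


def train_linear_discriminant(
    positives: np.ndarray,
    negatives: np.ndarray,
    feature_names: Sequence[str],
    ridge: float = 1e-6,
) -> DiscriminantCoefficients:
    """Two-class Fisher linear discriminant.

    weights = pooled-covariance^-1 (mean_pos - mean_neg); the intercept
    places the decision value 0 at the midpoint of the projected class
    means, so positives score > 0 on average. A ridge term stabilizes a
    near-singular pooled covariance; a covariance singular even after the
    ridge raises MixtureError.
    """
    pos = np.atleast_2d(np.asarray(positives, dtype=float))
    neg = np.atleast_2d(np.asarray(negatives, dtype=float))
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise MixtureError("each class needs >= 2 rows to train a discriminant")
    mean_pos = pos.mean(axis=0)
    mean_neg = neg.mean(axis=0)
    n_pos, n_neg = pos.shape[0], neg.shape[0]
    cov_pos = np.cov(pos, rowvar=False, bias=False)
    cov_neg = np.cov(neg, rowvar=False, bias=False)
    pooled = ((n_pos - 1) * np.atleast_2d(cov_pos) + (n_neg - 1) * np.atleast_2d(cov_neg)) / (
        n_pos + n_neg - 2
    )
    pooled = pooled + ridge * np.eye(pooled.shape[0])
    try:
        w = np.linalg.solve(pooled, mean_pos - mean_neg)
    except np.linalg.LinAlgError as exc:
        raise MixtureError("pooled covariance singular even after ridge") from exc
    midpoint = (mean_pos + mean_neg) / 2.0
    intercept = -float(np.dot(w, midpoint))
    return DiscriminantCoefficients(
        engine="custom",
        charge=0,
        intercept=intercept,
        weights={name: float(wi) for name, wi in zip(feature_names, w)},
    )


def select_best_candidates(
    candidate_sets: Sequence[CandidateSet],
    coeffs: DiscriminantCoefficients,
    top_k: int,
) -> PSMTable:
    """Score each spectrum's top-K candidates and keep the highest scorer.

    Ties go to the lowest original rank. The promoted record keeps its
    original rank field but receives the new discriminant score; the
    returned table holds one record per spectrum.
    """
    best: list[PSMRecord] = []
    for cs in candidate_sets:
        pool = cs.candidates[:top_k]
        scores = [score_record(c, coeffs) for c in pool]
        winner = int(np.argmax(scores))  # argmax returns the first (lowest-rank) maximum
        rec = replace(pool[winner], discriminant_score=float(scores[winner]))
        best.append(rec)
    return PSMTable(records=best)


def _coeff_vector(coeffs: DiscriminantCoefficients, names: list[str]) -> np.ndarray:
    return np.array([coeffs.intercept] + [coeffs.weights[n] for n in names])


def fit_adaptive(
    candidate_sets: Sequence[CandidateSet],
    init_coeffs: DiscriminantCoefficients,
    options: AdaptiveOptions | None = None,
) -> tuple[DiscriminantCoefficients, FitResult]:
    """Iteratively re-learn discriminant coefficients from the data.

    Returns the averaged final coefficients and the mixture fit of the
    final round's best-candidate table. Raises MixtureError when a round
    produces an empty positive or negative training selection (relax
    pep_low/pep_high in that case). Non-convergence within
    ``options.max_rounds`` returns the last round's state (the fit's
    ``converged`` flags still describe the inner EM).
    """
    options = options or AdaptiveOptions()
    names = list(init_coeffs.weights.keys())
    coeffs = init_coeffs
    fit: FitResult | None = None

    for _round in range(options.max_rounds):
        # re-derive the generator from the master seed each round: when a
        # round's training selection stops changing, the subsamples (and
        # hence the averaged coefficients) repeat exactly, so the epsilon
        # stop is an exact fixed point rather than a noise floor
        rng = np.random.default_rng(options.seed)
        best = select_best_candidates(candidate_sets, coeffs, options.top_k)
        fit = fit_em(best, options.fit_options)
        pep = fit.pep_array(best)
        feats = np.array([[rec.features[n] for n in names] for rec in best.records])
        valid = ~np.isnan(pep)
        is_decoy = np.array([rec.is_decoy for rec in best.records])
        pos_mask = valid & (pep <= options.pep_low) & ~is_decoy
        neg_mask = valid & (pep >= options.pep_high)
        floor = min(options.min_training, max(2, int(valid.sum()) // 4))
        if pos_mask.sum() < floor:
            # pad with the lowest-PEP targets
            target_valid = np.where(valid & ~is_decoy)[0]
            if len(target_valid) >= floor:
                chosen = target_valid[np.argsort(pep[target_valid])[:floor]]
                pos_mask = np.zeros_like(pos_mask)
                pos_mask[chosen] = True
        if neg_mask.sum() < floor:
            candidates_valid = np.where(valid)[0]
            if len(candidates_valid) >= floor:
                chosen = candidates_valid[np.argsort(pep[candidates_valid])[-floor:]]
                neg_mask = np.zeros_like(neg_mask)
                neg_mask[chosen] = True
        if pos_mask.sum() < 2 or neg_mask.sum() < 2:
            raise MixtureError(
                f"adaptive round selected {int(pos_mask.sum())} positives / "
                f"{int(neg_mask.sum())} negatives; relax pep_low/pep_high"
            )
        positives = feats[pos_mask]
        negatives = feats[neg_mask]

        vectors = []
        n_sub = max(2, int(round(options.subsample_fraction * positives.shape[0])))
        for _i in range(options.n_resample):
            idx = rng.choice(positives.shape[0], size=n_sub, replace=False)
            sub = train_linear_discriminant(
                positives[idx], negatives, names, ridge=options.ridge
            )
            vectors.append(_coeff_vector(sub, names))
        avg = np.mean(vectors, axis=0)
        new_coeffs = DiscriminantCoefficients(
            engine="custom",
            charge=0,
            intercept=float(avg[0]),
            weights={n: float(v) for n, v in zip(names, avg[1:])},
        )
        delta = float(np.max(np.abs(avg - _coeff_vector(coeffs, names))))
        coeffs = new_coeffs
        if delta < options.epsilon:
            break

    best = select_best_candidates(candidate_sets, coeffs, options.top_k)
    fit = fit_em(best, options.fit_options)
    return coeffs, fit
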