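"""Kernel-density (semiparametric) estimation of the score components.

When the parametric Normal/Gamma shapes visibly misfit the observed
scores — a left-skewed correct component is the typical culprit — the
component densities can instead be estimated nonparametrically. Decoy
matches, known to be incorrect, provide a direct sample of the negative
component; target scores, weighted by their current probability of being
correct, provide the positive one. With unit weights the estimator
reduces to the classical form

    p(S | h) = 1/(n0 h) * sum_i K((S - S_i) / h)

with K the standard normal density and h the bandwidth. Because kernel
estimates can overfit small samples, the fit refuses to run on fewer
than 500 targets unless forced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from psmix.psm_data import PSMTable
from psmix.mixture import (
    ComponentDistribution,
    FitResult,
    MixtureError,
    MixtureModel,
    m_step_pi0,
)

__all__ = [
    "KernelDensityEstimate",
    "kde_density",
    "kde_tail",
    "select_bandwidth",
    "fit_semiparametric",
    "SemiparametricOptions",
]


@dataclass
class KernelDensityEstimate:
    """Weighted Gaussian-kernel density: support points, weights, bandwidth h."""

    points: np.ndarray
    weights: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.points.shape != self.weights.shape:
            raise ValueError("points and weights must have the same shape")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ValueError("weights must be non-negative with at least one positive entry")


_SQRT_2PI = float(np.sqrt(2.0 * np.pi))
_CHUNK = 512  # evaluation points per block, bounds the n_eval x n_points workspace


def kde_density(kde: KernelDensityEstimate, s) -> np.ndarray | float:
    """Weighted kernel density at ``s``.

    (1/(W h)) * sum_i w_i K((s - x_i)/h) with W = sum w_i; for unit
    weights this is exactly the 1/(n0 h) decoy-sample form. Evaluation is
    blocked so large point sets stay within a bounded workspace.
    """
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    out = np.empty_like(s_arr)
    norm = kde.weights.sum() * kde.bandwidth * _SQRT_2PI
    for start in range(0, len(s_arr), _CHUNK):
        block = s_arr[start : start + _CHUNK]
        z = (block[:, None] - kde.points[None, :]) / kde.bandwidth
        out[start : start + _CHUNK] = np.exp(-0.5 * z * z) @ kde.weights / norm
    return out if np.ndim(s) else float(out[0])


def kde_tail(kde: KernelDensityEstimate, t) -> np.ndarray | float:
    """Upper tail P(S > t) of the kernel mixture (exact Gaussian-CDF sum)."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t_arr)
    total = kde.weights.sum()
    for start in range(0, len(t_arr), _CHUNK):
        block = t_arr[start : start + _CHUNK]
        z = (block[:, None] - kde.points[None, :]) / kde.bandwidth
        out[start : start + _CHUNK] = stats.norm.sf(z) @ kde.weights / total
    return out if np.ndim(t) else float(out[0])


def _weighted_sd_iqr(points: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    w = weights / weights.sum()
    mean = float(np.dot(w, points))
    sd = float(np.sqrt(np.dot(w, (points - mean) ** 2)))
    order = np.argsort(points)
    cum = np.cumsum(w[order])
    q25 = float(points[order][np.searchsorted(cum, 0.25)])
    q75 = float(points[order][np.searchsorted(cum, 0.75)])
    return sd, q75 - q25


def select_bandwidth(points, weights=None, method: str = "silverman") -> float:
    """Choose a kernel bandwidth.

    ``silverman``: 0.9 * min(sd, IQR/1.34) * n_eff^(-1/5), with weighted
    sd/IQR and effective sample size n_eff = (sum w)^2 / sum w^2.
    ``cv``: maximize the leave-one-out log-likelihood over a log-spaced
    grid around the silverman value.
    """
    points = np.asarray(points, dtype=float)
    weights = np.ones_like(points) if weights is None else np.asarray(weights, dtype=float)
    pos = weights > 0
    if len(np.unique(points[pos])) < 2:
        raise MixtureError("bandwidth selection requires >= 2 distinct weighted points")
    sd, iqr = _weighted_sd_iqr(points, weights)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = sd
    n_eff = weights.sum() ** 2 / np.dot(weights, weights)
    h_silverman = 0.9 * spread * n_eff ** (-0.2)
    if method == "silverman":
        return float(h_silverman)
    if method != "cv":
        raise ValueError(f"unknown bandwidth method {method!r}")

    # leave-one-out CV: for each point, density from all other points
    grid = h_silverman * np.logspace(-1.0, 0.7, 18)
    x = points[pos]
    w = weights[pos]
    diff = x[:, None] - x[None, :]
    best_h, best_ll = float(h_silverman), -np.inf
    for h in grid:
        k = stats.norm.pdf(diff / h) * w[None, :]
        np.fill_diagonal(k, 0.0)
        loo = k.sum(axis=1) / ((w.sum() - w) * h)
        ll = float(np.dot(w, np.log(np.maximum(loo, 1e-300))))
        if ll > best_ll:
            best_ll, best_h = ll, float(h)
    return best_h


@dataclass
class SemiparametricOptions:
    """Options for the kernel-component fit."""

    bandwidth_method: str = "silverman"
    min_decoys: int = 50
    min_records: int = 100
    min_targets_unforced: int = 500  # overfitting guardrail
    force: bool = False
    epsilon: float = 1e-4
    max_iterations: int = 200
    init_pi0: float = 0.9
    # records at or above this PEP are excluded from the positive KDE's
    # support: without the truncation the (1-PEP)-weighted mass of the many
    # confidently-incorrect targets leaks into the positive density and
    # biases pi0 downward
    positive_weight_cutoff: float = 0.9


def fit_semiparametric(
    table: PSMTable, options: SemiparametricOptions | None = None
) -> FitResult:
    """Fit kernel-density components per charge using decoys as the negative sample.

    Iteration: the negative KDE is built once from decoy scores (unit
    weights) and held fixed; the positive KDE is rebuilt from target
    scores weighted by the current (1 - PEP), zeroing records whose PEP
    exceeds ``positive_weight_cutoff`` (the first iteration, starting from
    a flat PEP, falls back to the untruncated weights); pi0 is the mean
    target PEP; PEPs are recomputed from the kernel mixture. Stops when no
    PEP moves by more than epsilon. Decoy PEPs are pinned at 1 and
    excluded from pi0.
    """
    options = options or SemiparametricOptions()
    models: dict[int, MixtureModel] = {}
    pep_out: dict[int, float] = {}
    n_iter: dict[int, int] = {}
    converged: dict[int, bool] = {}
    trace: dict[int, list[dict[str, float]]] = {}
    skipped: list[int] = []

    indexed = [
        (i, rec) for i, rec in enumerate(table.records) if rec.discriminant_score is not None
    ]
    for charge in sorted({rec.charge for _, rec in indexed}):
        items = [(i, rec) for i, rec in indexed if rec.charge == charge]
        scores = np.array([rec.discriminant_score for _, rec in items])
        is_decoy = np.array([rec.is_decoy for _, rec in items])
        n_decoys = int(is_decoy.sum())
        n_targets = int((~is_decoy).sum())
        if n_decoys < options.min_decoys:
            raise MixtureError(
                f"charge {charge}: {n_decoys} decoys < min_decoys={options.min_decoys}; "
                "use the parametric (or semisupervised parametric) fit instead"
            )
        if n_targets < options.min_records:
            raise MixtureError(
                f"charge {charge}: {n_targets} targets < min_records={options.min_records}"
            )
        if n_targets < options.min_targets_unforced and not options.force:
            raise MixtureError(
                f"charge {charge}: {n_targets} targets < {options.min_targets_unforced}; "
                "kernel fits overfit small samples — pass force=True to override"
            )

        decoy_scores = scores[is_decoy]
        target_scores = scores[~is_decoy]
        h0 = select_bandwidth(decoy_scores, method=options.bandwidth_method)
        neg_kde = KernelDensityEstimate(
            points=decoy_scores, weights=np.ones_like(decoy_scores), bandwidth=h0
        )
        f0_t = np.asarray(kde_density(neg_kde, target_scores))

        pi0 = options.init_pi0
        pep_t = np.full(n_targets, pi0)
        conv = False
        iters = 0
        tr: list[dict[str, float]] = []
        pos_kde = None
        for iteration in range(1, options.max_iterations + 1):
            iters = iteration
            w1 = (1.0 - pep_t) * (pep_t < options.positive_weight_cutoff)
            if w1.sum() <= 0:
                w1 = np.clip(1.0 - pep_t, 1e-12, 1.0)
            h1 = select_bandwidth(target_scores, w1, method=options.bandwidth_method)
            pos_kde = KernelDensityEstimate(points=target_scores, weights=w1, bandwidth=h1)
            f1_t = np.asarray(kde_density(pos_kde, target_scores))
            num = pi0 * f0_t
            den = num + (1.0 - pi0) * f1_t
            new_pep = np.where(den > 0, num / np.maximum(den, 1e-300), pi0)
            pi0 = m_step_pi0(new_pep)
            delta = float(np.max(np.abs(new_pep - pep_t)))
            pep_t = new_pep
            tr.append({"pi0": pi0, "h_pos": h1, "max_pep_delta": delta})
            if delta < options.epsilon:
                conv = True
                break

        model = MixtureModel(
            charge=charge,
            pi0=pi0,
            negative=ComponentDistribution(kind="kernel", kde=neg_kde),
            positive=ComponentDistribution(kind="kernel", kde=pos_kde),
        )
        models[charge] = model
        n_iter[charge] = iters
        converged[charge] = conv
        trace[charge] = tr
        t_idx = 0
        for idx, rec in items:
            if rec.is_decoy:
                pep_out[idx] = 1.0
            else:
                pep_out[idx] = float(np.clip(pep_t[t_idx], 0.0, 1.0))
                t_idx += 1

    return FitResult(
        models=models,
        pep=pep_out,
        n_iterations=n_iter,
        converged=converged,
        trace=trace,
        skipped_charges=skipped,
    )
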