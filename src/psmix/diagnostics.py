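"""Bootstrap stability diagnostics and quantile-quantile data.

A mixture fit on few spectra, or on scores that deviate from the assumed
shapes, can be unstable. Resampling the records with replacement and
refitting exposes this: per parameter, the spread of the B bootstrap
estimates gives a variance, the offset of their mean from the original
estimate gives a bias, and MSE = variance + bias^2 summarizes both.
100-500 resamples are recommended. Visual inspection (histograms,
quantile-quantile plots) is preferred over formal goodness-of-fit tests,
which collapse location-specific misfit into one number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from psmix.psm_data import PSMTable
from psmix.mixture import FitOptions, FitResult, MixtureError, fit_em

__all__ = ["BootstrapResult", "bootstrap_fit", "qq_pairs"]


@dataclass
class BootstrapResult:
    """Resampled parameter estimates with bias/variance/MSE summaries.

    ``estimates[name]`` holds the B (minus failures) resampled values of
    parameter ``name`` (named ``charge<z>.<param>``); ``original`` the
    full-data estimates; ``summaries[name]`` a (bias, variance, mse)
    triple with mse = variance + bias^2.
    """

    estimates: dict[str, np.ndarray]
    original: dict[str, float]
    summaries: dict[str, tuple[float, float, float]]
    B: int
    seed: int
    n_failures: int = 0
    metadata: dict = field(default_factory=dict)


def _flatten_params(fit: FitResult) -> dict[str, float]:
    out: dict[str, float] = {}
    for charge, model in fit.models.items():
        for name, value in model.param_vector().items():
            out[f"charge{charge}.{name}"] = value
    return out


def bootstrap_fit(
    table: PSMTable,
    options: FitOptions | None = None,
    B: int = 100,
    seed: int = 0,
    max_failure_fraction: float = 0.2,
) -> BootstrapResult:
    """Refit the mixture on B with-replacement resamples of the records.

    Resampling is stratified by charge (each charge keeps its record
    count), since models are fit per charge and pooling would mix them.
    Resamples whose fit degenerates are excluded with a warning; more
    than ``max_failure_fraction`` failures raises.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    options = options or FitOptions()
    base_fit = fit_em(table, options)
    original = _flatten_params(base_fit)
    rng = np.random.default_rng(seed)

    by_charge: dict[int, list[int]] = {}
    for i, rec in enumerate(table.records):
        by_charge.setdefault(rec.charge, []).append(i)

    estimates: dict[str, list[float]] = {name: [] for name in original}
    n_failures = 0
    for _ in range(B):
        chosen: list[int] = []
        for charge, idxs in sorted(by_charge.items()):
            idxs = np.asarray(idxs)
            chosen.extend(rng.choice(idxs, size=len(idxs), replace=True).tolist())
        resample = [table.records[i] for i in chosen]
        # re-key spectrum ids so the resample passes uniqueness validation
        resample = [
            type(rec)(
                spectrum_id=f"bs{j}",
                charge=rec.charge,
                features=rec.features,
                discriminant_score=rec.discriminant_score,
                ntt=rec.ntt,
                nmc=rec.nmc,
                delta_mass=rec.delta_mass,
                is_decoy=rec.is_decoy,
                peptide=rec.peptide,
                protein=rec.protein,
                rank=1,
                true_label=rec.true_label,
            )
            for j, rec in enumerate(resample)
        ]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_em(PSMTable(records=resample), options)
            params = _flatten_params(fit)
        except MixtureError:
            n_failures += 1
            continue
        if set(params) != set(original):
            n_failures += 1  # a charge was skipped in the resample
            continue
        for name, value in params.items():
            estimates[name].append(value)

    if n_failures > max_failure_fraction * B:
        raise MixtureError(
            f"{n_failures}/{B} bootstrap refits failed (> {max_failure_fraction:.0%})"
        )
    if n_failures:
        warnings.warn(f"{n_failures}/{B} bootstrap refits failed and were excluded", stacklevel=2)

    est_arrays = {name: np.asarray(vals) for name, vals in estimates.items()}
    summaries: dict[str, tuple[float, float, float]] = {}
    for name, vals in est_arrays.items():
        bias = float(vals.mean() - original[name])
        variance = float(vals.var(ddof=1)) if len(vals) > 1 else 0.0
        summaries[name] = (bias, variance, variance + bias * bias)
    return BootstrapResult(
        estimates=est_arrays,
        original=original,
        summaries=summaries,
        B=B,
        seed=seed,
        n_failures=n_failures,
    )


def qq_pairs(sample_a, sample_b, n_quantiles: int = 100) -> list[tuple[float, float]]:
    """Matched quantile pairs (Q_a(p), Q_b(p)) at p = k/n_quantiles, k=1..n_quantiles.

    Empirical quantiles use linear interpolation between order statistics.
    Points near the diagonal indicate agreement of the two distributions
    at that quantile.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    ps = np.arange(1, n_quantiles + 1) / n_quantiles
    qa = np.quantile(a, ps)
    qb = np.quantile(b, ps)
    return list(zip(qa.tolist(), qb.tolist()))
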