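"""Two-component mixture model of PSM scores, fitted by EM.

The score population of identified spectra is modeled per precursor
charge as

    S ~ pi0 * f0(S) + (1 - pi0) * f1(S)

where f1 is Normal(mu, sigma) for correctly identified spectra and f0 is
a shifted Gamma (or, alternatively, a Gumbel) for incorrect ones; pi0 is
the proportion of incorrect identifications. Auxiliary discrete features
(number of tryptic termini, missed cleavages, binned precursor-mass
error) enter as per-component multinomial factors, conditionally
independent of the score given the component.

Fitting alternates an E-step (Bayes posterior of being incorrect, the
PEP) with closed-form M-steps:

    pi0    = mean of the PEPs
    Normal weighted MLE with weights (1 - p_i), biased-variance form
    Gamma  shift = min score; method of moments on the shifted scores
           with weights p_i (alpha = m1^2/m2, rate beta = m1/m2)

until no parameter moves by more than epsilon (default 1e-4).

In the semisupervised (target-decoy) variant, decoy matches — known to
be incorrect — are pinned at PEP = 1 on every iteration and contribute
only to the negative component's updates, never to pi0, the Normal, or
the positive-side discrete tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from psmix.psm_data import PSMTable

__all__ = [
    "ComponentDistribution",
    "DiscreteFeatureTable",
    "MixtureModel",
    "FitOptions",
    "FitResult",
    "MixtureError",
    "DegenerateComponentError",
    "component_density",
    "component_tail",
    "e_step",
    "m_step_pi0",
    "m_step_normal",
    "m_step_gamma",
    "m_step_gumbel",
    "m_step_discrete",
    "fit_em",
    "log_likelihood",
    "EULER_GAMMA",
]

EULER_GAMMA = float(np.euler_gamma)

#: PEP clamp applied inside the EM loop only (reported PEPs are raw).
_CLAMP = 1e-12


class MixtureError(RuntimeError):
    """Base class for mixture-fitting failures."""


class DegenerateComponentError(MixtureError):
    """A component collapsed (zero variance / zero weight)."""


@dataclass
class ComponentDistribution:
    """One mixture component: normal, shifted_gamma, gumbel or kernel.

    Parameter slots by kind:

    * ``normal``: ``mu``, ``sigma`` (> 0)
    * ``shifted_gamma``: ``alpha`` (shape > 0), ``beta`` (RATE > 0),
      ``shift`` (support starts at ``shift``; mean = shift + alpha/beta)
    * ``gumbel``: ``location``, ``scale`` (> 0); max-extreme-value form,
      variance = scale^2 * pi^2 / 6
    * ``kernel``: ``kde`` holds a
      :class:`psmix.semiparametric.KernelDensityEstimate`
    """

    kind: str
    mu: float | None = None
    sigma: float | None = None
    alpha: float | None = None
    beta: float | None = None
    shift: float | None = None
    location: float | None = None
    scale: float | None = None
    kde: object | None = None

    def __post_init__(self) -> None:
        if self.kind == "normal":
            if self.mu is None or self.sigma is None or self.sigma <= 0:
                raise ValueError("normal requires mu and sigma > 0")
        elif self.kind == "shifted_gamma":
            if (
                self.alpha is None
                or self.beta is None
                or self.shift is None
                or self.alpha <= 0
                or self.beta <= 0
            ):
                raise ValueError("shifted_gamma requires alpha > 0, beta > 0 and a shift")
        elif self.kind == "gumbel":
            if self.location is None or self.scale is None or self.scale <= 0:
                raise ValueError("gumbel requires location and scale > 0")
        elif self.kind == "kernel":
            if self.kde is None:
                raise ValueError("kernel requires a KernelDensityEstimate")
        else:
            raise ValueError(f"unknown component kind {self.kind!r}")

    def params(self) -> dict[str, float]:
        """Flat name -> value map of the active parameters."""
        if self.kind == "normal":
            return {"mu": self.mu, "sigma": self.sigma}
        if self.kind == "shifted_gamma":
            return {"alpha": self.alpha, "beta": self.beta, "shift": self.shift}
        if self.kind == "gumbel":
            return {"location": self.location, "scale": self.scale}
        return {}

    def mean(self) -> float:
        if self.kind == "normal":
            return self.mu
        if self.kind == "shifted_gamma":
            return self.shift + self.alpha / self.beta
        if self.kind == "gumbel":
            return self.location + self.scale * EULER_GAMMA
        raise ValueError(f"no closed-form mean for kind {self.kind!r}")

    def std(self) -> float:
        if self.kind == "normal":
            return self.sigma
        if self.kind == "shifted_gamma":
            return math.sqrt(self.alpha) / self.beta
        if self.kind == "gumbel":
            return self.scale * math.pi / math.sqrt(6.0)
        raise ValueError(f"no closed-form std for kind {self.kind!r}")


def gumbel_std(scale: float) -> float:
    """Standard deviation of a Gumbel with the given scale: scale*pi/sqrt(6)."""
    return scale * math.pi / math.sqrt(6.0)


@dataclass
class DiscreteFeatureTable:
    """Per-component multinomial over one discrete feature's levels."""

    feature: str  # "ntt", "nmc" or "delta_mass_bin"
    levels: list
    p_incorrect: np.ndarray
    p_correct: np.ndarray

    def __post_init__(self) -> None:
        self.p_incorrect = np.asarray(self.p_incorrect, dtype=float)
        self.p_correct = np.asarray(self.p_correct, dtype=float)
        for name, vec in (("p_incorrect", self.p_incorrect), ("p_correct", self.p_correct)):
            if len(vec) != len(self.levels):
                raise ValueError(f"{name} length does not match levels")
            if np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector summing to 1")

    def prob(self, level, component: int) -> float:
        """P(level | T=component); returns 1.0 for an unseen level (factor skipped)."""
        try:
            idx = self.levels.index(level)
        except ValueError:
            return 1.0
        return float(self.p_incorrect[idx] if component == 0 else self.p_correct[idx])


@dataclass
class MixtureModel:
    """Fitted two-component mixture for one charge."""

    charge: int
    pi0: float
    negative: ComponentDistribution
    positive: ComponentDistribution
    discrete_features: list[DiscreteFeatureTable] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError(f"pi0 must be in [0,1], got {self.pi0}")

    def param_vector(self) -> dict[str, float]:
        out = {"pi0": self.pi0}
        out.update({f"negative.{k}": v for k, v in self.negative.params().items()})
        out.update({f"positive.{k}": v for k, v in self.positive.params().items()})
        return out


@dataclass
class FitOptions:
    """EM fitting options shared by the CLI and the library."""

    negative_family: str = "shifted_gamma"  # or "gumbel"
    use_decoys: bool = False  # semisupervised target-decoy constraint
    discrete_features: tuple[str, ...] = ()  # subset of ("ntt", "nmc", "delta_mass_bin")
    epsilon: float = 1e-4
    max_iterations: int = 1000
    min_records: int = 100
    delta_mass_bin_width: float = 1.0
    init_pi0: float = 0.9


@dataclass
class FitResult:
    """Per-charge fitted models plus per-record posteriors and trace."""

    models: dict[int, MixtureModel]
    pep: dict[int, float]  # table record index -> PEP
    n_iterations: dict[int, int]
    converged: dict[int, bool]
    trace: dict[int, list[dict[str, float]]]
    skipped_charges: list[int] = field(default_factory=list)

    def pep_array(self, table: PSMTable) -> np.ndarray:
        """PEPs aligned to table order (NaN for records of skipped charges)."""
        out = np.full(len(table.records), np.nan)
        for idx, p in self.pep.items():
            out[idx] = p
        return out


# ---------------------------------------------------------------------------
# densities and tails


def component_density(dist: ComponentDistribution, s) -> np.ndarray | float:
    """Probability density of a component at score(s) ``s``.

    The shifted Gamma has density 0 below its shift; the Gumbel uses the
    max-extreme-value form (1/scale) * exp(-z - e^-z), z = (s - location)/scale.
    """
    s_arr = np.asarray(s, dtype=float)
    if dist.kind == "normal":
        out = stats.norm.pdf(s_arr, loc=dist.mu, scale=dist.sigma)
    elif dist.kind == "shifted_gamma":
        out = stats.gamma.pdf(s_arr, a=dist.alpha, loc=dist.shift, scale=1.0 / dist.beta)
    elif dist.kind == "gumbel":
        out = stats.gumbel_r.pdf(s_arr, loc=dist.location, scale=dist.scale)
    elif dist.kind == "kernel":
        from psmix.semiparametric import kde_density

        out = kde_density(dist.kde, s_arr)
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown component kind {dist.kind!r}")
    return out if np.ndim(s) else float(out)


def component_tail(dist: ComponentDistribution, t) -> np.ndarray | float:
    """Upper tail P(S > t) of a component (survival function)."""
    t_arr = np.asarray(t, dtype=float)
    if dist.kind == "normal":
        out = stats.norm.sf(t_arr, loc=dist.mu, scale=dist.sigma)
    elif dist.kind == "shifted_gamma":
        out = stats.gamma.sf(t_arr, a=dist.alpha, loc=dist.shift, scale=1.0 / dist.beta)
    elif dist.kind == "gumbel":
        out = stats.gumbel_r.sf(t_arr, loc=dist.location, scale=dist.scale)
    elif dist.kind == "kernel":
        from psmix.semiparametric import kde_tail

        out = kde_tail(dist.kde, t_arr)
    else:  # pragma: no cover
        raise ValueError(f"unknown component kind {dist.kind!r}")
    return out if np.ndim(t) else float(out)


# ---------------------------------------------------------------------------
# E-step


def e_step(
    model: MixtureModel,
    score: float,
    discrete_levels: dict[str, object] | None = None,
) -> float:
    """Posterior probability of being incorrect (the PEP) at one score.

    PEP = pi0*f0(s)*prod(f0,feat) / (pi0*f0(s)*prod(f0,feat)
                                     + (1-pi0)*f1(s)*prod(f1,feat))

    Discrete factors are included only for tables present in the model
    and levels present on the record (absent levels contribute factor 1).

    Raises
    ------
    DegenerateComponentError
        When both mixture terms are exactly 0 at ``s``.
    """
    f0 = component_density(model.negative, score)
    f1 = component_density(model.positive, score)
    g0 = g1 = 1.0
    if discrete_levels:
        for table in model.discrete_features:
            level = discrete_levels.get(table.feature)
            if level is None:
                continue
            g0 *= table.prob(level, 0)
            g1 *= table.prob(level, 1)
    num = model.pi0 * f0 * g0
    den = num + (1.0 - model.pi0) * f1 * g1
    if den == 0.0:
        raise DegenerateComponentError(f"both mixture terms are 0 at score {score}")
    return num / den


def _e_step_vector(
    pi0: float,
    f0: np.ndarray,
    f1: np.ndarray,
    g0: np.ndarray,
    g1: np.ndarray,
) -> np.ndarray:
    num = pi0 * f0 * g0
    den = num + (1.0 - pi0) * f1 * g1
    bad = den == 0.0
    if np.any(bad):
        # both densities underflowed; fall back to the prior
        den = np.where(bad, 1.0, den)
        num = np.where(bad, pi0, num)
    return num / den


# ---------------------------------------------------------------------------
# M-steps


def m_step_pi0(pep: Sequence[float]) -> float:
    """pi0 estimate: the arithmetic mean of the membership probabilities."""
    pep = np.asarray(pep, dtype=float)
    if pep.size == 0:
        raise MixtureError("cannot estimate pi0 from an empty PEP vector")
    return float(pep.mean())


def m_step_normal(scores: Sequence[float], pep: Sequence[float]) -> tuple[float, float]:
    """Weighted-MLE Normal update with weights (1 - p_i).

    mu    = sum (1-p_i) s_i / sum (1-p_i)
    sigma = sqrt( sum (1-p_i)(s_i - mu)^2 / sum (1-p_i) )

    (biased form: the variance shares the mean's denominator).
    """
    scores = np.asarray(scores, dtype=float)
    w = 1.0 - np.asarray(pep, dtype=float)
    total = w.sum()
    if total <= 0:
        raise MixtureError("all positive-component weights are 0")
    mu = float(np.dot(w, scores) / total)
    var = float(np.dot(w, (scores - mu) ** 2) / total)
    if var <= 0:
        raise DegenerateComponentError("positive component collapsed to zero variance")
    return mu, math.sqrt(var)


def m_step_gamma(scores: Sequence[float], pep: Sequence[float]) -> tuple[float, float, float]:
    """Shifted-Gamma update: shift = min score; weighted method of moments.

    m1 = sum p_i (s_i - shift) / sum p_i
    m2 = sum p_i (s_i - shift - m1)^2 / sum p_i
    alpha = m1^2 / m2,  beta = m1 / m2   (beta is a rate)
    """
    scores = np.asarray(scores, dtype=float)
    w = np.asarray(pep, dtype=float)
    total = w.sum()
    if total <= 0:
        raise MixtureError("all negative-component weights are 0")
    shift = float(scores.min())
    centered = scores - shift
    m1 = float(np.dot(w, centered) / total)
    m2 = float(np.dot(w, (centered - m1) ** 2) / total)
    if m2 <= 0 or m1 <= 0:
        raise DegenerateComponentError("negative component collapsed (zero moment)")
    return m1 * m1 / m2, m1 / m2, shift


def m_step_gumbel(scores: Sequence[float], pep: Sequence[float]) -> tuple[float, float]:
    """Weighted method-of-moments Gumbel update.

    From the weighted mean m and variance v:
    scale = sqrt(6 v) / pi,  location = m - scale * euler_gamma.
    """
    scores = np.asarray(scores, dtype=float)
    w = np.asarray(pep, dtype=float)
    total = w.sum()
    if total <= 0:
        raise MixtureError("all negative-component weights are 0")
    m = float(np.dot(w, scores) / total)
    v = float(np.dot(w, (scores - m) ** 2) / total)
    if v <= 0:
        raise DegenerateComponentError("negative component collapsed (zero variance)")
    scale = math.sqrt(6.0 * v) / math.pi
    return m - scale * EULER_GAMMA, scale


def m_step_discrete(
    levels: Sequence,
    pep: Sequence[float],
    feature: str = "feature",
    incorrect_mask: Sequence[bool] | None = None,
    correct_mask: Sequence[bool] | None = None,
) -> DiscreteFeatureTable:
    """Weighted multinomial update of one discrete feature's tables.

    p_incorrect(level) is the PEP-weighted frequency of the level;
    p_correct uses weights (1 - PEP). The optional masks restrict which
    records contribute to each side (used by the semisupervised fit,
    where decoys feed only the incorrect side).
    """
    levels_arr = np.asarray(levels, dtype=object)
    pep_arr = np.asarray(pep, dtype=float)
    inc = np.ones(len(levels_arr), dtype=bool) if incorrect_mask is None else np.asarray(incorrect_mask, bool)
    cor = np.ones(len(levels_arr), dtype=bool) if correct_mask is None else np.asarray(correct_mask, bool)
    uniq = sorted(set(levels_arr.tolist()))
    w0_total = pep_arr[inc].sum()
    w1_total = (1.0 - pep_arr[cor]).sum()
    if w0_total <= 0 or w1_total <= 0:
        raise MixtureError(f"a component has zero total weight for feature {feature!r}")
    p0 = np.array([pep_arr[inc & (levels_arr == lv)].sum() for lv in uniq]) / w0_total
    p1 = np.array([(1.0 - pep_arr[cor & (levels_arr == lv)]).sum() for lv in uniq]) / w1_total
    return DiscreteFeatureTable(feature=feature, levels=uniq, p_incorrect=p0, p_correct=p1)


# ---------------------------------------------------------------------------
# likelihood and initialization


def log_likelihood(model: MixtureModel, scores: np.ndarray) -> float:
    """Observed-data log-likelihood of the score mixture (no discrete factors)."""
    f0 = component_density(model.negative, scores)
    f1 = component_density(model.positive, scores)
    mix = model.pi0 * f0 + (1.0 - model.pi0) * f1
    return float(np.sum(np.log(np.maximum(mix, 1e-300))))


def _init_components(
    scores: np.ndarray, family: str, init_pi0: float
) -> tuple[ComponentDistribution, ComponentDistribution]:
    """Moment-based starting point: Normal from the top decile of scores,
    negative family from the bottom half. Incorrect matches dominate
    typical searches, so the bulk informs the negative component."""
    srt = np.sort(scores)
    n = len(srt)
    top = srt[max(0, int(0.9 * n)) :]
    bottom = srt[: max(2, n // 2)]
    mu = float(top.mean())
    sigma = float(top.std()) or float(scores.std()) or 1.0
    positive = ComponentDistribution(kind="normal", mu=mu, sigma=max(sigma, 1e-3))
    if family == "shifted_gamma":
        shift = float(scores.min())
        centered = bottom - shift
        m1 = max(float(centered.mean()), 1e-6)
        m2 = max(float(centered.var()), 1e-12)
        negative = ComponentDistribution(
            kind="shifted_gamma", alpha=m1 * m1 / m2, beta=m1 / m2, shift=shift
        )
    elif family == "gumbel":
        m = float(bottom.mean())
        v = max(float(bottom.var()), 1e-12)
        scale = math.sqrt(6.0 * v) / math.pi
        negative = ComponentDistribution(
            kind="gumbel", location=m - scale * EULER_GAMMA, scale=scale
        )
    else:
        raise ValueError(f"unknown negative family {family!r}")
    return negative, positive


def _bin_delta_mass(dm: float, width: float) -> int:
    """Discretize a mass error into integer-indexed bins centered on multiples of width."""
    return int(np.floor(dm / width + 0.5))


def _record_levels(rec, options: FitOptions) -> dict[str, object]:
    levels: dict[str, object] = {}
    for feat in options.discrete_features:
        if feat == "ntt" and rec.ntt is not None:
            levels["ntt"] = rec.ntt
        elif feat == "nmc" and rec.nmc is not None:
            levels["nmc"] = rec.nmc
        elif feat == "delta_mass_bin" and rec.delta_mass is not None:
            levels["delta_mass_bin"] = _bin_delta_mass(rec.delta_mass, options.delta_mass_bin_width)
    return levels


# ---------------------------------------------------------------------------
# EM driver


def fit_em(table: PSMTable, options: FitOptions | None = None) -> FitResult:
    """Fit the per-charge two-component mixture by EM.

    Charges with fewer than ``options.min_records`` scored records are
    skipped with a warning (recorded in ``FitResult.skipped_charges``).
    With ``options.use_decoys`` the fit is semisupervised: decoy PEPs are
    pinned to 1 and decoys inform only the negative component.
    """
    options = options or FitOptions()
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
        charge_items = [(i, rec) for i, rec in indexed if rec.charge == charge]
        if len(charge_items) < options.min_records:
            warnings.warn(
                f"charge {charge}: only {len(charge_items)} scored records "
                f"(< {options.min_records}); skipping",
                stacklevel=2,
            )
            skipped.append(charge)
            continue
        model, pep_vec, iters, conv, tr = _fit_single_charge(charge_items, charge, options)
        models[charge] = model
        n_iter[charge] = iters
        converged[charge] = conv
        trace[charge] = tr
        for (idx, _), p in zip(charge_items, pep_vec):
            pep_out[idx] = float(p)

    return FitResult(
        models=models,
        pep=pep_out,
        n_iterations=n_iter,
        converged=converged,
        trace=trace,
        skipped_charges=skipped,
    )


def _fit_single_charge(charge_items, charge: int, options: FitOptions):
    recs = [rec for _, rec in charge_items]
    scores = np.array([rec.discriminant_score for rec in recs], dtype=float)
    if np.ptp(scores) == 0:
        raise DegenerateComponentError(f"charge {charge}: all scores identical")
    is_decoy = np.array([rec.is_decoy for rec in recs], dtype=bool)
    target = ~is_decoy
    semisup = options.use_decoys and is_decoy.any()

    level_maps = [_record_levels(rec, options) for rec in recs]
    feature_levels: dict[str, np.ndarray] = {}
    feature_present: dict[str, np.ndarray] = {}
    for feat in options.discrete_features:
        vals = np.array([lm.get(feat) for lm in level_maps], dtype=object)
        present = np.array([v is not None for v in vals], dtype=bool)
        if present.sum() >= 2:
            feature_levels[feat] = vals
            feature_present[feat] = present

    negative, positive = _init_components(scores, options.negative_family, options.init_pi0)
    pi0 = options.init_pi0
    tables: dict[str, DiscreteFeatureTable] = {}
    tr: list[dict[str, float]] = []
    conv = False
    iters = 0

    for iteration in range(1, options.max_iterations + 1):
        iters = iteration
        f0 = np.asarray(component_density(negative, scores))
        f1 = np.asarray(component_density(positive, scores))
        g0 = np.ones_like(scores)
        g1 = np.ones_like(scores)
        for feat, tab in tables.items():
            vals, present = feature_levels[feat], feature_present[feat]
            for lv_idx, lv in enumerate(tab.levels):
                mask = present & (vals == lv)
                g0[mask] *= tab.p_incorrect[lv_idx]
                g1[mask] *= tab.p_correct[lv_idx]

        pep = _e_step_vector(pi0, f0, f1, g0, g1)
        pep = np.clip(pep, _CLAMP, 1.0 - _CLAMP)
        if semisup:
            pep[is_decoy] = 1.0

        old = {"pi0": pi0, **negative.params(), **positive.params()}

        # pi0 and the Normal come from targets only under the decoy constraint
        pi0 = m_step_pi0(pep[target] if semisup else pep)
        mu, sigma = m_step_normal(scores[target] if semisup else scores,
                                  pep[target] if semisup else pep)
        positive = ComponentDistribution(kind="normal", mu=mu, sigma=sigma)
        if options.negative_family == "shifted_gamma":
            alpha, beta, shift = m_step_gamma(scores, pep)
            negative = ComponentDistribution(
                kind="shifted_gamma", alpha=alpha, beta=beta, shift=shift
            )
        else:
            location, scale = m_step_gumbel(scores, pep)
            negative = ComponentDistribution(kind="gumbel", location=location, scale=scale)

        new_tables: dict[str, DiscreteFeatureTable] = {}
        for feat, vals in feature_levels.items():
            present = feature_present[feat]
            new_tables[feat] = m_step_discrete(
                vals[present],
                pep[present],
                feature=feat,
                incorrect_mask=np.ones(present.sum(), dtype=bool),
                correct_mask=(target if semisup else np.ones(len(recs), dtype=bool))[present],
            )
        tables = new_tables

        new = {"pi0": pi0, **negative.params(), **positive.params()}
        tr.append(dict(new))
        delta = max(abs(new[k] - old.get(k, np.inf)) for k in new)
        if delta < options.epsilon:
            conv = True
            break

    model = MixtureModel(
        charge=charge,
        pi0=pi0,
        negative=negative,
        positive=positive,
        discrete_features=list(tables.values()),
    )

    # final reported PEPs: raw E-step outputs at the converged parameters
    final_pep = np.array(
        [e_step(model, s, lm if lm else None) for s, lm in zip(scores, level_maps)]
    )
    if semisup:
        final_pep[is_decoy] = 1.0
    return model, final_pep, iters, conv, tr
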