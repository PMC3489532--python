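"""Synthetic PSM generator with ground-truth labels.

Generates score tables with exactly the statistical structure the
mixture model assumes, so every estimator in the package can be checked
against known truth: per charge, each target is incorrect with
probability pi0 (score drawn from the negative component, discrete
levels from the incorrect-side tables) and correct otherwise (positive
component, correct-side tables); decoys are additional draws from the
negative component flagged ``is_decoy``. Every record carries
``true_label``.

Limitations (by design): decoy counts are set independently of target
counts — the target/decoy competition of a concatenated search is not
modeled mechanistically — and raw-feature mode uses equal-covariance
Gaussian classes, making the Bayes-optimal score combiner exactly
linear.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from psmix.psm_data import PSMRecord, PSMTable
from psmix.mixture import ComponentDistribution, DiscreteFeatureTable

__all__ = [
    "ChargeBlock",
    "SimulationConfig",
    "simulate_psms",
    "simulate_candidate_sets",
    "true_fdr",
    "load_config",
]


@dataclass
class ChargeBlock:
    """Generative settings for one precursor charge."""

    charge: int
    pi0: float
    negative: ComponentDistribution
    positive: ComponentDistribution
    n_targets: int
    n_decoys: int = 0
    discrete_features: list[DiscreteFeatureTable] = field(default_factory=list)
    feature_mode: str = "score_only"  # or "raw_features"
    # raw-feature mode: class-conditional multivariate normals, shared covariance
    feature_names: tuple[str, ...] = ("f1", "f2", "f3")
    mean_incorrect: tuple[float, ...] = (0.0, 0.0, 0.0)
    mean_correct: tuple[float, ...] = (1.0, 1.0, 1.0)
    covariance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("pi0 must be in [0,1]")
        if self.n_targets < 0 or self.n_decoys < 0:
            raise ValueError("counts must be non-negative")
        if self.feature_mode not in ("score_only", "raw_features"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        if self.feature_mode == "raw_features" and self.covariance is None:
            self.covariance = np.eye(len(self.feature_names))


@dataclass
class SimulationConfig:
    """Per-charge generative blocks plus the master seed."""

    blocks: list[ChargeBlock]
    seed: int = 0


def _draw_component(dist: ComponentDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    if dist.kind == "normal":
        return rng.normal(dist.mu, dist.sigma, size=n)
    if dist.kind == "shifted_gamma":
        return dist.shift + rng.gamma(dist.alpha, 1.0 / dist.beta, size=n)
    if dist.kind == "gumbel":
        return rng.gumbel(dist.location, dist.scale, size=n)
    raise ValueError(f"cannot sample from component kind {dist.kind!r}")


def _draw_levels(
    tables: list[DiscreteFeatureTable], component: int, n: int, rng: np.random.Generator
) -> list[dict[str, object]]:
    out = [dict() for _ in range(n)]
    for tab in tables:
        probs = tab.p_incorrect if component == 0 else tab.p_correct
        draws = rng.choice(len(tab.levels), size=n, p=probs)
        for i, d in enumerate(draws):
            out[i][tab.feature] = tab.levels[int(d)]
    return out


def _apply_levels(kwargs: dict, levels: dict[str, object]) -> None:
    if "ntt" in levels:
        kwargs["ntt"] = int(levels["ntt"])
    if "nmc" in levels:
        kwargs["nmc"] = int(levels["nmc"])
    if "delta_mass_bin" in levels:
        kwargs["delta_mass"] = float(levels["delta_mass_bin"])


def simulate_psms(config: SimulationConfig) -> PSMTable:
    """Draw a labeled PSM table from the configured mixture structure.

    Fully reproducible from ``config.seed``. In ``raw_features`` mode each
    record carries class-conditional multivariate-normal engine features
    and no precomputed discriminant score (a score independent of the
    features would be inconsistent); apply a discriminant to score them.
    """
    rng = np.random.default_rng(config.seed)
    records: list[PSMRecord] = []
    counter = 0
    for block in config.blocks:
        is_incorrect = rng.random(block.n_targets) < block.pi0
        n0 = int(is_incorrect.sum())
        n1 = block.n_targets - n0
        scores = np.empty(block.n_targets)
        scores[is_incorrect] = _draw_component(block.negative, n0, rng)
        scores[~is_incorrect] = _draw_component(block.positive, n1, rng)
        levels = np.empty(block.n_targets, dtype=object)
        levels[is_incorrect] = _draw_levels(block.discrete_features, 0, n0, rng)
        levels[~is_incorrect] = _draw_levels(block.discrete_features, 1, n1, rng)

        feats = np.empty((block.n_targets, 0))
        decoy_feats = np.empty((block.n_decoys, 0))
        if block.feature_mode == "raw_features":
            cov = np.asarray(block.covariance, dtype=float)
            feats = np.empty((block.n_targets, len(block.feature_names)))
            if n0:
                feats[is_incorrect] = rng.multivariate_normal(
                    block.mean_incorrect, cov, size=n0
                )
            if n1:
                feats[~is_incorrect] = rng.multivariate_normal(block.mean_correct, cov, size=n1)
            decoy_feats = rng.multivariate_normal(block.mean_incorrect, cov, size=block.n_decoys)

        for i in range(block.n_targets):
            kwargs = dict(
                spectrum_id=f"sim_{counter}",
                charge=block.charge,
                discriminant_score=float(scores[i]),
                is_decoy=False,
                true_label="incorrect" if is_incorrect[i] else "correct",
            )
            _apply_levels(kwargs, levels[i])
            if block.feature_mode == "raw_features":
                kwargs["features"] = {
                    name: float(feats[i, j]) for j, name in enumerate(block.feature_names)
                }
                kwargs["discriminant_score"] = None
            records.append(PSMRecord(**kwargs))
            counter += 1

        decoy_scores = _draw_component(block.negative, block.n_decoys, rng)
        decoy_levels = _draw_levels(block.discrete_features, 0, block.n_decoys, rng)
        for i in range(block.n_decoys):
            kwargs = dict(
                spectrum_id=f"sim_{counter}",
                charge=block.charge,
                discriminant_score=float(decoy_scores[i]),
                is_decoy=True,
                protein="rev_SYNTH",
                true_label="incorrect",
            )
            _apply_levels(kwargs, decoy_levels[i])
            if block.feature_mode == "raw_features":
                kwargs["features"] = {
                    name: float(decoy_feats[i, j]) for j, name in enumerate(block.feature_names)
                }
                kwargs["discriminant_score"] = None
            records.append(PSMRecord(**kwargs))
            counter += 1

    return PSMTable(
        records=records,
        metadata={"generator": "psmix.synth", "seed": config.seed},
    )


def simulate_candidate_sets(
    n_spectra: int,
    pi0: float,
    top_k: int = 5,
    n_decoy_spectra: int = 0,
    feature_names: tuple[str, ...] = ("f1", "f2", "f3"),
    mean_incorrect: tuple[float, ...] = (0.0, 0.0, 0.0),
    mean_correct: tuple[float, ...] = (2.0, 1.0, 0.5),
    covariance: np.ndarray | None = None,
    p_correct_rank1: float = 0.8,
    charge: int = 2,
    seed: int = 0,
):
    """Simulate per-spectrum top-K candidate lists for the adaptive workflow.

    Each target spectrum is correct with probability 1 - pi0. A correct
    spectrum hides one correct candidate (features from the correct-class
    Gaussian) at rank 1 with probability ``p_correct_rank1``, otherwise at
    a uniform lower rank; all other candidates — and every candidate of
    incorrect and decoy spectra — draw from the incorrect-class Gaussian.
    Shared covariance keeps the Bayes-optimal combiner linear, with true
    direction covariance^-1 (mean_correct - mean_incorrect).
    """
    from psmix.adaptive import CandidateSet

    rng = np.random.default_rng(seed)
    cov = np.eye(len(feature_names)) if covariance is None else np.asarray(covariance, float)
    sets = []

    def make_set(sid: str, correct_rank: int | None, is_decoy: bool) -> CandidateSet:
        cands = []
        for rank in range(1, top_k + 1):
            is_correct = correct_rank == rank
            mean = mean_correct if is_correct else mean_incorrect
            feats = rng.multivariate_normal(mean, cov)
            cands.append(
                PSMRecord(
                    spectrum_id=sid,
                    charge=charge,
                    features={n: float(v) for n, v in zip(feature_names, feats)},
                    is_decoy=is_decoy,
                    protein="rev_SYNTH" if is_decoy else None,
                    rank=rank,
                    true_label="correct" if is_correct else "incorrect",
                )
            )
        return CandidateSet(spectrum_id=sid, candidates=cands)

    for i in range(n_spectra):
        if rng.random() < pi0:
            correct_rank = None
        elif rng.random() < p_correct_rank1 or top_k == 1:
            correct_rank = 1
        else:
            correct_rank = int(rng.integers(2, top_k + 1))
        sets.append(make_set(f"spec_{i}", correct_rank, False))
    for i in range(n_decoy_spectra):
        sets.append(make_set(f"dspec_{i}", None, True))
    return sets


def true_fdr(table: PSMTable, t: float) -> float:
    """Label-based FDR at cutoff ``t``: incorrect targets above t / targets above t.

    Requires ground-truth labels (synthetic data); decoys are excluded.
    """
    above = [
        r
        for r in table.records
        if not r.is_decoy and r.discriminant_score is not None and r.discriminant_score > t
    ]
    if not above:
        raise ValueError(f"no target records above t={t}")
    if any(r.true_label is None for r in above):
        raise ValueError("true_fdr requires true_label on every target record")
    n_wrong = sum(1 for r in above if r.true_label == "incorrect")
    return n_wrong / len(above)


def mixture_cdf(block: ChargeBlock, s) -> np.ndarray | float:
    """CDF of the configured target-score mixture (for distributional checks)."""
    s_arr = np.asarray(s, dtype=float)

    def cdf(dist: ComponentDistribution):
        if dist.kind == "normal":
            return stats.norm.cdf(s_arr, dist.mu, dist.sigma)
        if dist.kind == "shifted_gamma":
            return stats.gamma.cdf(s_arr, a=dist.alpha, loc=dist.shift, scale=1.0 / dist.beta)
        if dist.kind == "gumbel":
            return stats.gumbel_r.cdf(s_arr, dist.location, dist.scale)
        raise ValueError(dist.kind)

    out = block.pi0 * cdf(block.negative) + (1 - block.pi0) * cdf(block.positive)
    return out if np.ndim(s) else float(out)


def load_config(path) -> SimulationConfig:
    """Load a SimulationConfig from a JSON file.

    Schema: {"seed": int, "blocks": [{"charge", "pi0", "n_targets",
    "n_decoys", "negative": {"kind", ...params}, "positive": {...},
    "discrete_features": [{"feature", "levels", "p_incorrect",
    "p_correct"}], "feature_mode", ...raw-feature keys}]}.
    """
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    blocks = []
    for b in data["blocks"]:
        blocks.append(
            ChargeBlock(
                charge=b["charge"],
                pi0=b["pi0"],
                negative=ComponentDistribution(**b["negative"]),
                positive=ComponentDistribution(**b["positive"]),
                n_targets=b["n_targets"],
                n_decoys=b.get("n_decoys", 0),
                discrete_features=[
                    DiscreteFeatureTable(
                        feature=t["feature"],
                        levels=t["levels"],
                        p_incorrect=np.asarray(t["p_incorrect"]),
                        p_correct=np.asarray(t["p_correct"]),
                    )
                    for t in b.get("discrete_features", [])
                ],
                feature_mode=b.get("feature_mode", "score_only"),
                feature_names=tuple(b.get("feature_names", ("f1", "f2", "f3"))),
                mean_incorrect=tuple(b.get("mean_incorrect", (0.0, 0.0, 0.0))),
                mean_correct=tuple(b.get("mean_correct", (1.0, 1.0, 1.0))),
                covariance=np.asarray(b["covariance"]) if "covariance" in b else None,
            )
        )
    return SimulationConfig(blocks=blocks, seed=data.get("seed", 0))
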