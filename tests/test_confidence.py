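"""Confidence measures: PEP, p-value/FPR identity, FDR estimators, q-values."""

import numpy as np
import pytest
from scipy import stats

from psmix.confidence import (
    build_confidence_table,
    fdr_decoy_ratio,
    fdr_mean_pep,
    fdr_model,
    fpr_at,
    p_value_at,
    pep_at,
    q_values,
)
from psmix.mixture import (
    ComponentDistribution,
    FitOptions,
    MixtureError,
    MixtureModel,
    DiscreteFeatureTable,
    e_step,
    fit_em,
)
from psmix.psm_data import PSMRecord, PSMTable
from psmix.synth import true_fdr


def make_model(pi0=0.5, mu=3.0, sigma=1.0, alpha=4.0, beta=2.0, shift=-3.0, **kw):
    return MixtureModel(
        charge=2,
        pi0=pi0,
        negative=ComponentDistribution(kind="shifted_gamma", alpha=alpha, beta=beta, shift=shift),
        positive=ComponentDistribution(kind="normal", mu=mu, sigma=sigma),
        **kw,
    )


def random_model(rng):
    return make_model(
        pi0=rng.uniform(0.05, 0.95),
        mu=rng.uniform(0, 4),
        sigma=rng.uniform(0.5, 2),
        alpha=rng.uniform(1, 6),
        beta=rng.uniform(0.5, 3),
        shift=rng.uniform(-6, -2),
    )


# ---------------------------------------------------------------------------
# point measures


def test_pep_at_symmetry_and_limit():
    same = MixtureModel(
        charge=2,
        pi0=0.5,
        negative=ComponentDistribution(kind="normal", mu=0.0, sigma=1.0),
        positive=ComponentDistribution(kind="normal", mu=0.0, sigma=1.0),
    )
    assert pep_at(same, 1.23) == pytest.approx(0.5)
    # far above both components with the positive dominating the tail
    # (fast-decaying rate-5 gamma vs a wide normal) the PEP vanishes
    heavy_pos = make_model(beta=5.0, sigma=2.0)
    assert pep_at(heavy_pos, 12.0) == pytest.approx(0.0, abs=1e-6)


def test_pep_at_matches_e_step(rng):
    for _ in range(20):
        model = random_model(rng)
        s = rng.uniform(-2, 6)
        assert pep_at(model, s) == pytest.approx(e_step(model, s), abs=1e-12)


def test_p_value_closed_forms():
    model = make_model(shift=-3.0)
    assert p_value_at(model, -3.0) == pytest.approx(1.0)
    assert p_value_at(model, 1e6) == pytest.approx(0.0)
    gumbel_model = MixtureModel(
        charge=2,
        pi0=0.5,
        negative=ComponentDistribution(kind="gumbel", location=0.0, scale=1.0),
        positive=ComponentDistribution(kind="normal", mu=3.0, sigma=1.0),
    )
    assert p_value_at(gumbel_model, 0.0) == pytest.approx(1.0 - np.exp(-1.0))


def test_fpr_is_identical_to_p_value(rng):
    """Set-level FPR and per-spectrum p-value are the same null tail."""
    for _ in range(100):
        model = random_model(rng)
        t = rng.uniform(-4, 6)
        assert fpr_at(model, t) == p_value_at(model, t)


def test_fpr_monotone_nonincreasing_and_median():
    model = make_model()
    median = stats.gamma.ppf(0.5, a=4.0, loc=-3.0, scale=0.5)
    assert fpr_at(model, median) == pytest.approx(0.5)
    grid = np.linspace(-3, 8, 200)
    values = np.asarray(fpr_at(model, grid))
    assert np.all(np.diff(values) <= 1e-12)


# ---------------------------------------------------------------------------
# FDR estimators


def test_fdr_model_symmetry_and_low_cutoff_limit():
    same = MixtureModel(
        charge=2,
        pi0=0.5,
        negative=ComponentDistribution(kind="normal", mu=0.0, sigma=1.0),
        positive=ComponentDistribution(kind="normal", mu=0.0, sigma=1.0),
    )
    for t in (-2.0, 0.0, 1.5):
        assert fdr_model(same, t) == pytest.approx(0.5)
    model = make_model(pi0=0.8)
    assert fdr_model(model, -1e6) == pytest.approx(0.8)


def test_fdr_model_conditional_on_nmc():
    nmc = DiscreteFeatureTable(
        feature="nmc", levels=[0, 1], p_incorrect=[0.404, 0.596], p_correct=[0.926, 0.074]
    )
    model = make_model(pi0=0.96, discrete_features=[nmc])
    for t in (0.0, 1.0, 2.0):
        unconditional = fdr_model(model, t)
        conditional = fdr_model(model, t, discrete_condition={"nmc": 0})
        # the incorrect class is much less likely to have 0 missed cleavages
        # (0.404 vs 0.926), so conditioning on NMC=0 lowers the FDR
        assert conditional < unconditional
        # closed-form check of the conditional ratio
        a0 = stats.gamma.sf(t, a=4.0, loc=-3.0, scale=0.5) * 0.404
        a1 = stats.norm.sf(t, 3.0, 1.0) * 0.926
        expected = 0.96 * a0 / (0.96 * a0 + 0.04 * a1)
        assert conditional == pytest.approx(expected, abs=1e-12)


def test_fdr_model_empty_rejection_region():
    model = make_model()
    with pytest.raises(MixtureError, match="empty rejection region"):
        fdr_model(model, 1e9)


def test_fdr_mean_pep_examples():
    assert fdr_mean_pep([0.1, 0.2, 0.3], [5.0, 6.0, 7.0], 1.0) == pytest.approx(0.2)
    assert fdr_mean_pep([0.7], [2.0], 2.0) == pytest.approx(0.7)
    with pytest.raises(MixtureError):
        fdr_mean_pep([0.1], [1.0], 2.0)


def test_fdr_decoy_ratio_counting():
    records = [
        PSMRecord(spectrum_id=f"t{i}", charge=2, discriminant_score=5.0) for i in range(50)
    ] + [
        PSMRecord(spectrum_id=f"d{i}", charge=2, discriminant_score=5.0, is_decoy=True)
        for i in range(5)
    ]
    table = PSMTable(records=records)
    assert fdr_decoy_ratio(table, 0.0) == pytest.approx(0.1)
    # decoys all below the cutoff -> 0
    for rec in records[50:]:
        rec.discriminant_score = -1.0
    assert fdr_decoy_ratio(table, 0.0) == pytest.approx(0.0)
    with pytest.raises(MixtureError):
        fdr_decoy_ratio(table, 10.0)


# ---------------------------------------------------------------------------
# q-values


def test_q_values_cumulative_minimum_example():
    fdrs = {1.0: 0.05, 2.0: 0.03, 3.0: 0.04}
    out = q_values([1.0, 2.0, 3.0], lambda c: fdrs[c])
    assert out == pytest.approx([0.05, 0.03, 0.03])


def test_q_values_equal_fdr_when_monotone():
    fdrs = {1.0: 0.05, 2.0: 0.04, 3.0: 0.01}
    out = q_values([1.0, 2.0, 3.0], lambda c: fdrs[c])
    assert out == pytest.approx([0.05, 0.04, 0.01])


def test_q_values_match_brute_force_oracle(rng):
    """Cumulative-min implementation vs explicit min over all cutoffs <= s."""
    for _ in range(1000):
        n = int(rng.integers(1, 12))
        scores = np.round(rng.normal(size=n), 3)
        fdr_map = {float(s): float(rng.uniform(0, 1)) for s in np.unique(scores)}
        out = q_values(scores, lambda c: fdr_map[float(c)])
        for s, q in zip(scores, out):
            brute = min(v for c, v in fdr_map.items() if c <= s)
            assert q == pytest.approx(brute, abs=0.0)


# ---------------------------------------------------------------------------
# estimator calibration on labeled simulation


def test_fdr_estimators_track_true_fdr(reference_table_with_decoys):
    """Model, mean-PEP and decoy-ratio FDR all within 0.02 of the label-based
    truth at cutoffs accepting >= 200 targets."""
    table = reference_table_with_decoys
    fit = fit_em(table, FitOptions(use_decoys=True))
    model = fit.models[2]
    target_idx = [i for i, r in enumerate(table.records) if not r.is_decoy]
    scores = np.array([table.records[i].discriminant_score for i in target_idx])
    peps = np.array([fit.pep[i] for i in target_idx])
    for t in np.arange(-1.0, 4.5, 0.25):
        n_accepted = int((scores > t).sum())
        if n_accepted < 200:
            continue
        truth = true_fdr(table, t)
        assert fdr_model(model, t) == pytest.approx(truth, abs=0.02)
        assert fdr_mean_pep(peps, scores, t) == pytest.approx(truth, abs=0.02)
        assert fdr_decoy_ratio(table, t) == pytest.approx(truth, abs=0.02)


# ---------------------------------------------------------------------------
# assembled table


def test_confidence_table_invariants(reference_table):
    fit = fit_em(reference_table)
    conf = build_confidence_table(fit, reference_table, fdr_method="model")
    order = np.argsort(conf.scores)
    assert np.all(np.diff(conf.q_value[order]) <= 1e-12)
    assert np.all((conf.pep >= 0) & (conf.pep <= 1))
    assert np.all((conf.q_value >= 0) & (conf.q_value <= 1))
    # pep column is the E-step re-evaluated at each score
    model = fit.models[2]
    for s, p in list(zip(conf.scores, conf.pep))[::500]:
        assert p == pytest.approx(e_step(model, s), abs=1e-9)


def test_confidence_table_mean_pep_agrees_with_model(reference_table):
    fit = fit_em(reference_table)
    q_model = build_confidence_table(fit, reference_table, "model").q_value
    q_mean = build_confidence_table(fit, reference_table, "mean_pep").q_value
    assert np.max(np.abs(q_model - q_mean)) < 0.02
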