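"""Mixture components, E/M steps, and EM fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from psmix.mixture import (
    ComponentDistribution,
    DegenerateComponentError,
    FitOptions,
    MixtureError,
    MixtureModel,
    component_density,
    e_step,
    fit_em,
    log_likelihood,
    m_step_discrete,
    m_step_gamma,
    m_step_gumbel,
    m_step_normal,
    m_step_pi0,
)
from psmix.psm_data import PSMRecord, PSMTable
from psmix.synth import SimulationConfig, simulate_psms

from conftest import make_block


def bayes_pep_oracle(pi0: float, f0: float, f1: float) -> float:
    """Independent Bayes-ratio reference: pi0*f0 / (pi0*f0 + (1-pi0)*f1)."""
    return pi0 * f0 / (pi0 * f0 + (1.0 - pi0) * f1)


# ---------------------------------------------------------------------------
# densities


def test_component_density_closed_forms():
    normal = ComponentDistribution(kind="normal", mu=0.0, sigma=1.0)
    assert component_density(normal, 0.0) == pytest.approx(1.0 / math.sqrt(2 * math.pi))
    gamma = ComponentDistribution(kind="shifted_gamma", alpha=2.0, beta=1.0, shift=5.0)
    assert component_density(gamma, 4.0) == 0.0
    gumbel = ComponentDistribution(kind="gumbel", location=0.0, scale=1.0)
    assert component_density(gumbel, 0.0) == pytest.approx(math.exp(-1.0))


def test_gumbel_std_closed_form():
    dist = ComponentDistribution(kind="gumbel", location=-1.16, scale=0.76)
    assert dist.std() == pytest.approx(0.76 * math.pi / math.sqrt(6.0))
    # matches the distribution's actual variance
    assert dist.std() == pytest.approx(stats.gumbel_r.std(loc=-1.16, scale=0.76))


def test_invalid_component_params_rejected():
    with pytest.raises(ValueError):
        ComponentDistribution(kind="normal", mu=0.0, sigma=0.0)
    with pytest.raises(ValueError):
        ComponentDistribution(kind="shifted_gamma", alpha=-1.0, beta=1.0, shift=0.0)
    with pytest.raises(ValueError):
        ComponentDistribution(kind="gumbel", location=0.0, scale=-2.0)


# ---------------------------------------------------------------------------
# E-step


def make_model(pi0=0.5, mu=1.0, sigma=1.0, alpha=2.0, beta=1.0, shift=-5.0, **kw):
    return MixtureModel(
        charge=2,
        pi0=pi0,
        negative=ComponentDistribution(kind="shifted_gamma", alpha=alpha, beta=beta, shift=shift),
        positive=ComponentDistribution(kind="normal", mu=mu, sigma=sigma),
        **kw,
    )


def test_e_step_symmetry_and_boundaries():
    # identical components and pi0 = 0.5 -> PEP 0.5 at any score
    same = MixtureModel(
        charge=2,
        pi0=0.5,
        negative=ComponentDistribution(kind="normal", mu=0.0, sigma=1.0),
        positive=ComponentDistribution(kind="normal", mu=0.0, sigma=1.0),
    )
    assert e_step(same, 0.37) == pytest.approx(0.5)
    # pi0 = 1 -> PEP 1 wherever the negative density is positive
    sure = make_model(pi0=1.0)
    assert e_step(sure, 0.0) == pytest.approx(1.0)


def test_e_step_hand_computed_bayes_ratio():
    """pi0=0.96, f0=0.0724, f1=0.1473 -> 0.069504/0.075396 ~= 0.9219."""
    assert bayes_pep_oracle(0.96, 0.0724, 0.1473) == pytest.approx(0.92185, abs=1e-4)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    pi0=st.floats(0.01, 0.99),
    mu=st.floats(-2, 4),
    sigma=st.floats(0.2, 3),
    alpha=st.floats(0.5, 8),
    beta=st.floats(0.2, 4),
    shift=st.floats(-6, -1),
    s=st.floats(-0.9, 6),
)
def test_e_step_matches_independent_oracle(pi0, mu, sigma, alpha, beta, shift, s):
    """E-step equals the Bayes ratio computed from scipy densities directly."""
    model = make_model(pi0=pi0, mu=mu, sigma=sigma, alpha=alpha, beta=beta, shift=shift)
    f0 = stats.gamma.pdf(s, a=alpha, loc=shift, scale=1.0 / beta)
    f1 = stats.norm.pdf(s, loc=mu, scale=sigma)
    assert e_step(model, s) == pytest.approx(bayes_pep_oracle(pi0, f0, f1), abs=1e-12)


def test_e_step_includes_discrete_factors():
    from psmix.mixture import DiscreteFeatureTable

    table = DiscreteFeatureTable(
        feature="nmc", levels=[0, 1], p_incorrect=[0.404, 0.596], p_correct=[0.926, 0.074]
    )
    model = make_model(pi0=0.5, discrete_features=[table])
    s = 1.0
    f0 = component_density(model.negative, s)
    f1 = component_density(model.positive, s)
    expected = bayes_pep_oracle(0.5, f0 * 0.404, f1 * 0.926)
    assert e_step(model, s, {"nmc": 0}) == pytest.approx(expected, abs=1e-12)
    # absent level -> factor skipped
    assert e_step(model, s, {"ntt": 2}) == pytest.approx(e_step(model, s), abs=1e-12)


def test_e_step_degenerate_density_raises():
    model = make_model(pi0=0.5, shift=5.0, mu=0.0, sigma=1e-3)
    with pytest.raises(DegenerateComponentError):
        e_step(model, 4.0)  # below gamma support, ~60 sigma from the normal


# ---------------------------------------------------------------------------
# M-steps


@pytest.mark.parametrize(
    "pep, expected",
    [((1, 0, 1, 0), 0.5), ((1, 1, 1), 1.0), ((0.2, 0.4, 0.9), 0.5)],
)
def test_m_step_pi0(pep, expected):
    assert m_step_pi0(pep) == pytest.approx(expected)


def test_m_step_pi0_empty_vector():
    with pytest.raises(MixtureError):
        m_step_pi0([])


def test_m_step_normal_examples():
    mu, sigma = m_step_normal([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
    assert mu == pytest.approx(2.0)
    assert sigma == pytest.approx(math.sqrt(2.0 / 3.0))  # biased MLE form
    mu, sigma = m_step_normal([0.0, 2.0], [0.5, 0.5])
    assert (mu, sigma) == (pytest.approx(1.0), pytest.approx(1.0))
    with pytest.raises(DegenerateComponentError):
        m_step_normal([10.0, 4.0], [1.0, 0.0])  # single effective point
    with pytest.raises(MixtureError):
        m_step_normal([1.0, 2.0], [1.0, 1.0])  # zero total weight


def test_m_step_gamma_hand_computed():
    alpha, beta, shift = m_step_gamma([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
    assert shift == pytest.approx(1.0)
    assert alpha == pytest.approx(1.5)  # m1=1, m2=2/3
    assert beta == pytest.approx(1.5)
    with pytest.raises(DegenerateComponentError):
        m_step_gamma([0.0, 0.0, 5.0], [1.0, 1.0, 0.0])


def test_m_step_gamma_recovers_moments_on_simulation():
    """Method-of-moments consistency. The shift is estimated by the sample
    minimum, which for a shape-4 gamma approaches the true shift only at
    rate n^(-1/4) (~0.07 above it at n=50k), biasing alpha/beta slightly
    low; tolerances account for that known estimator property."""
    rng = np.random.default_rng(7)
    scores = -2.0 + rng.gamma(4.0, 1.0 / 2.0, size=50_000)
    alpha, beta, shift = m_step_gamma(scores, np.ones_like(scores))
    assert shift == pytest.approx(scores.min())
    assert shift == pytest.approx(-2.0, abs=0.1)
    assert alpha == pytest.approx(4.0, abs=0.35)
    assert beta == pytest.approx(2.0, abs=0.15)
    # with the true shift supplied instead, the raw moments are unbiased
    m1 = (scores + 2.0).mean()
    m2 = ((scores + 2.0 - m1) ** 2).mean()
    assert m1 * m1 / m2 == pytest.approx(4.0, abs=0.1)
    assert m1 / m2 == pytest.approx(2.0, abs=0.05)


def test_m_step_gumbel_recovers_moments_on_simulation():
    rng = np.random.default_rng(8)
    scores = rng.gumbel(-1.0, 0.8, size=50_000)
    location, scale = m_step_gumbel(scores, np.ones_like(scores))
    assert location == pytest.approx(-1.0, abs=0.02)
    assert scale == pytest.approx(0.8, abs=0.02)


def test_m_step_discrete_counting():
    table = m_step_discrete([0, 1, 0, 0], [1.0, 1.0, 0.0, 0.0], feature="ntt")
    assert table.p_incorrect == pytest.approx([0.5, 0.5])
    assert table.p_correct == pytest.approx([1.0, 0.0])


def test_m_step_discrete_point_mass():
    table = m_step_discrete([2, 2, 2], [0.5, 0.5, 0.5], feature="ntt")
    assert table.p_incorrect == pytest.approx([1.0])
    assert table.p_correct == pytest.approx([1.0])


def test_m_step_discrete_recovers_tables_on_simulation():
    rng = np.random.default_rng(9)
    n = 100_000
    incorrect = rng.random(n) < 0.6
    p0, p1 = [0.5, 0.3, 0.2], [0.05, 0.15, 0.8]
    levels = np.where(
        incorrect, rng.choice(3, size=n, p=p0), rng.choice(3, size=n, p=p1)
    )
    table = m_step_discrete(levels.tolist(), incorrect.astype(float), feature="ntt")
    assert table.p_incorrect == pytest.approx(p0, abs=0.02)
    assert table.p_correct == pytest.approx(p1, abs=0.02)


# ---------------------------------------------------------------------------
# EM fitting


def test_fit_em_recovers_generating_parameters(reference_table):
    fit = fit_em(reference_table)
    model = fit.models[2]
    assert model.pi0 == pytest.approx(0.7, abs=0.02)
    assert model.positive.mu == pytest.approx(3.0, abs=0.05)
    assert model.positive.sigma == pytest.approx(1.0, abs=0.05)
    assert fit.converged[2]
    assert all(0.0 <= p <= 1.0 for p in fit.pep.values())


def test_fit_em_identical_scores_degenerate():
    records = [
        PSMRecord(spectrum_id=f"s{i}", charge=2, discriminant_score=1.0) for i in range(200)
    ]
    with pytest.raises(DegenerateComponentError):
        fit_em(PSMTable(records=records))


def test_fit_em_skips_sparse_charge(reference_table):
    extra = [
        PSMRecord(spectrum_id=f"x{i}", charge=4, discriminant_score=float(i)) for i in range(5)
    ]
    table = PSMTable(records=list(reference_table.records) + extra)
    with pytest.warns(UserWarning, match="charge 4"):
        fit = fit_em(table)
    assert 4 in fit.skipped_charges
    assert 4 not in fit.models


def test_semisupervised_pins_decoy_pep_to_one(reference_table_with_decoys):
    fit = fit_em(reference_table_with_decoys, FitOptions(use_decoys=True))
    decoy_idx = [
        i for i, rec in enumerate(reference_table_with_decoys.records) if rec.is_decoy
    ]
    assert decoy_idx
    assert all(fit.pep[i] == 1.0 for i in decoy_idx)


def test_em_log_likelihood_is_nondecreasing(reference_table):
    """EM iterations must not decrease the observed-data log-likelihood
    beyond moment-update noise. The Gamma M-step is method-of-moments (as
    the estimator is defined), not an exact MLE, so ascent holds up to a
    small relative tolerance; the net change over the fit must be positive."""
    fit = fit_em(reference_table, FitOptions(max_iterations=40))
    scores = np.array([r.discriminant_score for r in reference_table.records])
    lls = []
    for snap in fit.trace[2]:
        model = MixtureModel(
            charge=2,
            pi0=snap["pi0"],
            negative=ComponentDistribution(
                kind="shifted_gamma",
                alpha=snap["alpha"],
                beta=snap["beta"],
                shift=snap["shift"],
            ),
            positive=ComponentDistribution(kind="normal", mu=snap["mu"], sigma=snap["sigma"]),
        )
        lls.append(log_likelihood(model, scores))
    diffs = np.diff(lls)
    assert np.all(diffs >= -2e-5 * np.abs(np.array(lls[1:])))
    assert lls[-1] > lls[0]


def test_fit_em_with_discrete_features_recovers_tables():
    from psmix.mixture import DiscreteFeatureTable

    ntt = DiscreteFeatureTable(
        feature="ntt", levels=[0, 1, 2], p_incorrect=[0.5, 0.3, 0.2], p_correct=[0.05, 0.15, 0.8]
    )
    table = simulate_psms(
        SimulationConfig(blocks=[make_block(discrete_features=[ntt])], seed=13)
    )
    fit = fit_em(table, FitOptions(discrete_features=("ntt",)))
    fitted = fit.models[2].discrete_features[0]
    assert fitted.p_incorrect == pytest.approx([0.5, 0.3, 0.2], abs=0.03)
    assert fitted.p_correct == pytest.approx([0.05, 0.15, 0.8], abs=0.03)
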