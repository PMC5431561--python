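"""Amplitude laws: moments, samplers and Laplace kernels."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from shotspike import (
    DeltaDist,
    ExponentialDist,
    TruncGaussDist,
    UniformDist,
    laplace_kernel_Q,
    parse_dist,
)

DISTS = {
    "delta": DeltaDist(a_i=-1.0),
    "exp": ExponentialDist(a_scale=1.0, sign=-1),
    "uniform": UniformDist(l1=-2.0, l2=0.0),
    "tgauss": TruncGaussDist(a_p=-0.7766, sigma_G=0.7766),
    "tgauss_wide": TruncGaussDist(a_p=-1.0, sigma_G=2.0),
}


@pytest.mark.parametrize("name", ["exp", "uniform", "tgauss", "tgauss_wide"])
def test_pdf_normalization_and_quadrature_moments(name):
    """The density integrates to one and its quadrature moments match the
    closed forms to 1e-8."""
    d = DISTS[name]
    lo = -40.0
    mass = integrate.quad(lambda a: d.pdf(a), lo, 0.0, limit=200)[0]
    assert mass == pytest.approx(1.0, abs=1e-8)
    m1 = integrate.quad(lambda a: a * d.pdf(a), lo, 0.0, limit=200)[0]
    m2 = integrate.quad(lambda a: a * a * d.pdf(a), lo, 0.0, limit=200)[0]
    m3 = integrate.quad(lambda a: a**3 * d.pdf(a), lo, 0.0, limit=200)[0]
    assert m1 == pytest.approx(d.mean, abs=1e-8)
    assert m2 - m1 * m1 == pytest.approx(d.variance, abs=1e-8)
    mu3 = m3 - 3 * m2 * m1 + 2 * m1**3
    assert mu3 / d.variance**1.5 == pytest.approx(d.skewness, abs=1e-7)


def test_known_moment_values():
    assert DeltaDist(a_i=-1.0).moments() == (-1.0, 0.0, 0.0)
    m, v, g = ExponentialDist(a_scale=1.0, sign=-1).moments()
    assert (m, v, g) == (-1.0, 1.0, -2.0)
    u = UniformDist(l1=-2.0, l2=0.0)
    assert u.mean == -1.0
    assert u.variance == pytest.approx(4.0 / 12.0)
    assert u.skewness == 0.0


def test_tgd_moments_match_scipy_truncnorm():
    """Closed-form truncated-Gaussian moments against scipy's truncnorm."""
    for ap, sg in [(-1.0, 0.5), (-1.0, 5.0), (-0.7766, 0.7766)]:
        d = TruncGaussDist(a_p=ap, sigma_G=sg)
        ref = stats.truncnorm(-np.inf, -ap / sg, loc=ap, scale=sg)
        m, v, g, *_ = (*ref.stats(moments="mvs"),)
        assert d.mean == pytest.approx(float(m), rel=1e-10)
        assert d.variance == pytest.approx(float(v), rel=1e-10)
        assert d.skewness == pytest.approx(float(g), rel=1e-8)


def test_tgd_skewness_large_width_limit():
    """sigma_G -> infinity approaches the (negative) half-normal skewness."""
    half_normal = -np.sqrt(2) * (4 - np.pi) / (np.pi - 2) ** 1.5
    d = TruncGaussDist(a_p=-1.0, sigma_G=1e4)
    assert d.skewness == pytest.approx(half_normal, abs=1e-3)


@pytest.mark.parametrize("name", sorted(DISTS))
def test_sampler_matches_moments(name):
    """Empirical moments of 10^6 draws within 5 standard errors."""
    d = DISTS[name]
    rng = np.random.default_rng(1234)
    x = d.sample(1_000_000, rng)
    n = len(x)
    se_mean = np.sqrt(max(d.variance, 1e-30) / n)
    assert abs(x.mean() - d.mean) <= 5 * se_mean + 1e-12
    if d.variance > 0:
        mu4 = np.mean((x - x.mean()) ** 4)
        se_var = np.sqrt((mu4 - x.var() ** 2) / n)
        assert abs(x.var() - d.variance) <= 5 * se_var


def test_sampler_support():
    rng = np.random.default_rng(0)
    u = UniformDist(l1=-2.0, l2=0.0)
    x = u.sample(100_000, rng)
    assert x.min() >= -2.0 and x.max() <= 0.0
    t = DISTS["tgauss"].sample(100_000, rng)
    assert t.max() <= 0.0
    assert np.all(DeltaDist(a_i=-1.5).sample(5, rng) == -1.5)


def test_delta_kernel_hand_value():
    """Q(s) for delta kicks at a_i=-1, R=0.1/ms, s=1."""
    q = laplace_kernel_Q(DeltaDist(a_i=-1.0), 0.1, 1.0)
    assert q == pytest.approx(-0.1 * (1 - np.exp(-1.0)), rel=1e-12)


@pytest.mark.parametrize("name", sorted(DISTS))
def test_kernel_small_s_limit_is_mean(name):
    """Q(s)/R -> <a> as s -> 0+, approached at the m2*s/2 slope."""
    d = DISTS[name]
    m1, m2, _ = d.raw_moments()
    assert d.kernel(1e-10) == pytest.approx(m1, rel=1e-8)
    for s in (1e-7, 1e-4):
        assert d.kernel(s) - m1 == pytest.approx(m2 * s / 2, rel=1e-2)
    # and the kernel integral has the matching slope
    assert d.kernel_integral(1e-6) == pytest.approx(m1 * 1e-6, rel=1e-5)


@pytest.mark.parametrize("name", ["delta", "exp", "uniform", "tgauss"])
def test_kernel_integral_matches_quadrature(name):
    """psi(s) = ∫_0^s Q/R dc: closed/precomputed forms vs direct quadrature."""
    d = DISTS[name]
    for s_hi in (0.5, 3.0):
        ref = integrate.quad(lambda c: float(d.kernel(c)), 0, s_hi, limit=200)[0]
        assert float(d.kernel_integral(s_hi)) == pytest.approx(ref, abs=1e-9, rel=1e-9)


def test_tgd_kernel_stable_vs_literal_and_asymptotic():
    """The erfcx rewriting equals the literal kernel where the latter is
    finite, and the large-argument asymptotic branch agrees to <1%."""
    d = TruncGaussDist(a_p=-1.0, sigma_G=2.0)
    s_mod = np.array([0.1, 0.5, 1.0, 2.0])
    assert np.allclose(d.kernel(s_mod), d.kernel_eq46(s_mod), rtol=1e-10)
    s_big = np.array([3.0, 5.0, 10.0])
    rel = np.abs(d.kernel_asymptotic(s_big) / d.kernel(s_big) - 1.0)
    assert rel.max() < 0.01
    # the stable form stays finite far beyond the literal form's overflow
    assert np.isfinite(d.kernel(np.array([500.0, 5000.0]))).all()


def test_excitatory_kernel_pole():
    d = ExponentialDist(a_scale=1.0, sign=1)
    assert d.kernel(0.5) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        d.kernel(1.0)


@pytest.mark.parametrize(
    "text", ["delta:a=-1", "exp:a=-1", "uniform:l1=-2,l2=0", "tgauss:ap=-0.7766,sg=0.7766"]
)
def test_parse_roundtrip(text):
    d = parse_dist(text)
    assert parse_dist(d.spec_string()).moments() == d.moments()


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    ap=st.floats(-3.0, -0.1),
    sg=st.floats(0.1, 5.0),
    s=st.floats(1e-4, 4.0),
)
def test_tgd_kernel_is_node_average(ap, sg, s):
    """The closed-form kernel equals the quadrature average of the delta
    kernel over the amplitude nodes (consistency of the two routes)."""
    d = TruncGaussDist(a_p=ap, sigma_G=sg)
    nodes, w = d._nodes()
    direct = np.dot(w, np.expm1(s * nodes) / s)
    assert float(d.kernel(s)) == pytest.approx(direct, rel=1e-6, abs=1e-9)
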