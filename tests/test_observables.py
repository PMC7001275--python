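"""Observables: profiles, enhancement, fits, scaling, re-integration law.

Oracles are hand-countable synthetic event sets and closed-form power-law /
exponential inputs whose recovered parameters are known exactly.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tepolymer as tp
from tepolymer.integration import ExperimentResult, IntegrationEvent, TESpec
from tepolymer.observables import (EnhancementEstimate, FrequencyProfile,
                                   ScalingCurve, distribution_median,
                                   fit_scaling_exponent,
                                   reintegration_distance_pdf)
from tepolymer.sampler import EnsembleSample
from tepolymer.substrate import PolymerConformation, SubstrateSpec


def _result_from_loci(loci, n_beads=20, flagged=0):
    events = [IntegrationEvent(i, l, -1.0, 5, 100 + i)
              for i, l in enumerate(loci)]
    for j in range(flagged):
        events.append(IntegrationEvent(len(loci) + j, -1, float("nan"), 9,
                                       999 + j, flagged=True))
    return ExperimentResult(events=events, spec=SubstrateSpec(n_beads=n_beads),
                            te=TESpec(), n_replicates=len(events))


# ---------------------------------------------------------------- profiles

def test_frequency_profile_counting():
    # [TRIVIAL] 4 events at loci {3, 3, 5, 5} on 20 beads
    prof = tp.frequency_profile(_result_from_loci([3, 3, 5, 5]))
    assert prof.n_loci == 19
    assert prof.n_events == 4
    assert prof.freqs[3] == prof.freqs[5] == 0.5
    assert prof.freqs.sum() == pytest.approx(1.0)
    assert prof.counts[3] == 2


def test_frequency_profile_excludes_flagged():
    prof = tp.frequency_profile(_result_from_loci([3, 3, 5, 5], flagged=3))
    assert prof.n_events == 4


def test_frequency_profile_no_events_raises():
    with pytest.raises(ValueError):
        tp.frequency_profile(_result_from_loci([], flagged=2))


def test_profile_validation():
    with pytest.raises(ValueError):
        FrequencyProfile(freqs=np.array([0.5, 0.4]), n_events=10,
                         se=np.zeros(2))  # does not sum to 1
    with pytest.raises(ValueError):
        FrequencyProfile(freqs=np.array([1.2, -0.2]), n_events=10,
                         se=np.zeros(2))


# ------------------------------------------------------------- enhancement

def _uniform_profile(n_loci, n_events=1000):
    f = np.full(n_loci, 1.0 / n_loci)
    return FrequencyProfile(freqs=f, n_events=n_events,
                            se=np.sqrt(f * (1 - f) / n_events),
                            counts=f * n_events)


def test_enhancement_uniform_is_exactly_one():
    prof = _uniform_profile(199)
    enh = tp.soft_site_enhancement(prof, soft_indices=range(18, 60, 3))
    assert enh.value == pytest.approx(1.0, abs=1e-12)


def test_enhancement_concentrated_events():
    # [TRIVIAL] all events in 10 designated loci of 200 -> enhancement 20
    f = np.zeros(200)
    f[10:20] = 0.1
    prof = FrequencyProfile(freqs=f, n_events=500, se=np.zeros(200),
                            counts=f * 500)
    enh = tp.soft_site_enhancement(prof, soft_indices=range(10, 20))
    assert enh.value == pytest.approx(20.0)
    assert enh.n_soft == 10


def test_enhancement_fractional_share():
    # 30% of events in a 5-locus set of 100 loci -> 0.3 / (5/100) = 6
    f = np.full(100, 0.7 / 95)
    f[:5] = 0.06
    prof = FrequencyProfile(freqs=f, n_events=400, se=np.zeros(100),
                            counts=f * 400)
    enh = tp.soft_site_enhancement(prof, soft_indices=range(5))
    assert enh.value == pytest.approx(6.0)


def test_enhancement_n_insertable_override():
    f = np.zeros(10)
    f[4] = 1.0
    prof = FrequencyProfile(freqs=f, n_events=50, se=np.zeros(10),
                            counts=f * 50)
    a = tp.soft_site_enhancement(prof, [4])
    b = tp.soft_site_enhancement(prof, [4], n_insertable=8)
    assert a.value == pytest.approx(10.0)
    assert b.value == pytest.approx(8.0)


def test_enhancement_input_validation():
    prof = _uniform_profile(50)
    with pytest.raises(ValueError):
        tp.soft_site_enhancement(prof, [])
    with pytest.raises(ValueError):
        tp.soft_site_enhancement(prof, [50])


def test_uniformity_test_flat_and_peaked():
    flat = _uniform_profile(100, n_events=100 * 30)
    chi2, p = tp.uniformity_test(flat)
    assert chi2 == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)
    peaked = np.full(100, 20.0)
    peaked[7] = 400.0
    prof = FrequencyProfile(freqs=peaked / peaked.sum(),
                            n_events=int(peaked.sum()),
                            se=np.zeros(100), counts=peaked)
    _, p = tp.uniformity_test(prof)
    assert p < 1e-10


# --------------------------------------------------------- exponential fit

def test_exponential_fit_recovery():
    # [DERIVED] exact exponential input: enh = exp(a (lp - lf)), a = 0.02
    lf = np.array([150.0, 120.0, 90.0, 60.0])
    enh = np.exp(0.02 * (150.0 - lf))
    fit = tp.fit_enhancement_exponential(lf, enh)
    assert fit.rate_per_bp == pytest.approx(0.02, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)
    assert not fit.faster_than_exponential


def test_exponential_fit_flags_superexponential_tail():
    lf = np.array([150.0, 130.0, 110.0, 90.0, 70.0, 50.0])
    enh = np.exp(0.02 * (150.0 - lf))
    enh[-1] *= 4.0  # strongest softening jumps above the line
    fit = tp.fit_enhancement_exponential(lf, enh)
    assert fit.faster_than_exponential


def test_exponential_fit_constant_is_zero_rate():
    fit = tp.fit_enhancement_exponential([150.0, 100.0, 50.0],
                                         [1.0, 1.0, 1.0])
    assert fit.rate_per_bp == pytest.approx(0.0, abs=1e-12)


def test_exponential_fit_validation():
    with pytest.raises(ValueError):
        tp.fit_enhancement_exponential([150.0, 100.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        tp.fit_enhancement_exponential([150.0, 100.0, 50.0], [1.0, -1.0, 2.0])
    with pytest.raises(ValueError):
        tp.fit_enhancement_exponential([150.0, 100.0, 250.0], [1.0, 1.0, 1.0])


# ------------------------------------------------------- contact / scaling

def test_contact_probability_rod():
    # [DERIVED] straight rod: P_c(s) = 1 for s < cutoff, 0 beyond
    n = 30
    rod = PolymerConformation(
        np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)]))
    ens = EnsembleSample(frames=[rod] * 3, spec=None, sweeps_per_frame=1,
                         master_seed=0)
    pc = tp.contact_probability(ens, cutoff=2.5)
    assert np.allclose(pc.ordinate[:2], 1.0)
    assert np.allclose(pc.ordinate[3:], 0.0)


def test_contact_probability_brute_force_oracle():
    rng = np.random.default_rng(12)
    frames = [PolymerConformation(
        np.cumsum(rng.normal(scale=0.8, size=(25, 3)), axis=0))
        for _ in range(5)]
    ens = EnsembleSample(frames=frames, spec=None, sweeps_per_frame=1,
                         master_seed=0)
    cutoff = 2.0
    pc = tp.contact_probability(ens, cutoff=cutoff)
    # independent O(N^2) loop
    for s in (1, 4, 11, 24):
        hits, tot = 0, 0
        for f in frames:
            for i in range(25 - s):
                tot += 1
                hits += np.linalg.norm(f.coords[i + s] - f.coords[i]) < cutoff
        assert pc.ordinate[s - 1] == pytest.approx(hits / tot)
    assert np.all((pc.ordinate >= 0) & (pc.ordinate <= 1))


def test_fit_scaling_exponent_exact_power_laws():
    s = np.arange(2.0, 200.0)
    contact = ScalingCurve(abscissa=s, ordinate=s ** -1.5)
    fit = fit_scaling_exponent(contact, mode="contact")
    assert fit.nu == pytest.approx(0.5, abs=1e-6)
    length = np.array([50.0, 100.0, 200.0, 400.0])
    size = ScalingCurve(abscissa=length, ordinate=2.0 * length ** 0.6)
    fit = fit_scaling_exponent(size, mode="size")
    assert fit.nu == pytest.approx(0.6, abs=1e-9)


def test_asymptotic_contact_window_oracle():
    # [DERIVED] the closed-form ideal-chain contact probability is
    # P_c(s) = gammainc(3/2, 3 c^2 / (2 s)); inside the recommended window
    # its fitted exponent must be close to the true nu = 1/2, while the
    # naive small-s window is visibly biased by the crossover.
    from scipy.special import gammainc
    from tepolymer.observables import asymptotic_contact_window
    cutoff, n = 1.5, 400
    s = np.arange(1.0, n, dtype=float)
    exact = ScalingCurve(abscissa=s,
                         ordinate=gammainc(1.5, 3 * cutoff ** 2 / (2 * s)))
    win = asymptotic_contact_window(cutoff, n)
    assert win[0] == pytest.approx(15 * cutoff ** 2, abs=1)
    good = fit_scaling_exponent(exact, mode="contact", window=win)
    assert good.nu == pytest.approx(0.5, abs=0.02)
    naive = fit_scaling_exponent(exact, mode="contact", window=(4, n // 4))
    assert abs(naive.nu - 0.5) > abs(good.nu - 0.5)
    with pytest.raises(ValueError):
        asymptotic_contact_window(0.0, n)


def test_fit_scaling_exponent_window_and_validation():
    s = np.arange(1.0, 100.0)
    curve = ScalingCurve(abscissa=s, ordinate=s ** -2.0)
    fit = fit_scaling_exponent(curve, mode="contact", window=(5, 50))
    assert fit.window == (5.0, 50.0)
    assert fit.n_points == 46
    with pytest.raises(ValueError):
        fit_scaling_exponent(curve, mode="rouse")
    with pytest.raises(ValueError):
        fit_scaling_exponent(curve, mode="contact", window=(5, 7))


# --------------------------------------------------- re-integration range

def test_reintegration_pdf_two_point():
    # [DERIVED] nu = 1/3, support {1, 2}: weights 1 and 2^-1 -> (2/3, 1/3)
    s, p = reintegration_distance_pdf(1.0 / 3.0, 1, 2)
    assert p.tolist() == pytest.approx([2.0 / 3.0, 1.0 / 3.0])
    assert s.tolist() == [1.0, 2.0]


@settings(derandomize=True, max_examples=30)
@given(nu=st.floats(0.1, 1.0), span=st.integers(2, 500))
def test_reintegration_pdf_normalised(nu, span):
    _, p = reintegration_distance_pdf(nu, 1, 1 + span)
    assert p.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(p) <= 1e-15)  # monotone decreasing


def test_reintegration_median_ordering():
    # collapsed chromatin (nu = 1/3) re-integrates farther than ideal (1/2)
    s3, p3 = reintegration_distance_pdf(1.0 / 3.0, 1, 10_000)
    s2, p2 = reintegration_distance_pdf(0.5, 1, 10_000)
    assert distribution_median(s3, p3) > distribution_median(s2, p2)


def test_reintegration_pdf_validation():
    with pytest.raises(ValueError):
        reintegration_distance_pdf(0.0, 1, 10)
    with pytest.raises(ValueError):
        reintegration_distance_pdf(0.5, 10, 10)


# --------------------------------------------- consistency on real output

def test_profile_enhancement_identity_on_simulated_data(uniform_result):
    # pooled-profile enhancement equals the event-share computed directly
    prof = tp.frequency_profile(uniform_result)
    soft_loci = uniform_result.spec.soft_loci()
    enh = tp.soft_site_enhancement(prof, soft_loci, n_insertable=197)
    loci = np.array([e.locus for e in uniform_result.ok_events])
    share = np.isin(loci, soft_loci).mean()
    assert enh.value == pytest.approx(share / (len(soft_loci) / 197.0))


def test_simulated_events_land_on_interior_loci(uniform_result):
    loci = np.array([e.locus for e in uniform_result.ok_events])
    assert loci.min() >= 1
    assert loci.max() <= uniform_result.spec.n_beads - 3
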