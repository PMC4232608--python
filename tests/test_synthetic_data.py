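"""Generators: closed-form oracles, trivial limits, and determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circlekeeper import get_preset
from circlekeeper import nuclear_quant as nq
from circlekeeper import synthetic_data as sd
from circlekeeper.presets import CHI3_MEAN


# --- telophase segregation tallies -----------------------------------------

@pytest.mark.parametrize("p,expected", [(0.0, 100.0), (1.0, 0.0)])
def test_segregation_extreme_propagation(wt, p, expected):
    counts = sd.gen_segregation_counts(wt.replace(p_prop=p), 3000, seed=1)
    assert counts.a == counts.b == counts.c == expected


def test_segregation_binomial_closed_form(wt):
    # each of m plasmids retained with prob (1-p): category percentages
    # converge to 100*(1-p)**m
    counts = sd.gen_segregation_counts(wt.replace(p_prop=0.1), 100_000, seed=2)
    assert counts.a == pytest.approx(90.0, abs=0.5)
    assert counts.b == pytest.approx(81.0, abs=0.5)
    assert counts.c == pytest.approx(65.61, abs=2.0)  # only ~6% of cells
    assert counts.x + counts.y + counts.z == 100_000


def test_segregation_empty_category_undefined(wt):
    counts = sd.gen_segregation_counts(
        wt.replace(count_mix=(1.0, 0.0, 0.0)), 100, seed=3)
    assert counts.y == counts.z == 0
    assert counts.b is None and counts.c is None


@given(seed=st.integers(0, 2**31 - 1))
@settings(max_examples=15, deadline=None)
def test_segregation_deterministic_given_seed(seed):
    wt = get_preset("wt")
    c1 = sd.gen_segregation_counts(wt, 500, seed=seed)
    c2 = sd.gen_segregation_counts(wt, 500, seed=seed)
    assert (c1.x, c1.y, c1.z, c1.a, c1.b, c1.c) == \
        (c2.x, c2.y, c2.z, c2.a, c2.b, c2.c)


# --- nucleus images ---------------------------------------------------------

def test_nucleus_image_truth_block(noiseless_image_preset):
    img = sd.gen_nucleus_image(noiseless_image_preset, seed=4)
    for key in ("center", "radius_um", "cap_theta", "cap_span", "cap_ratio",
                "plasmid_theta", "background", "rim_total"):
        assert key in img.truth
    assert img.truth["cap_ratio"] == 2.02
    assert img.red is not None


def test_nucleus_image_rejects_bad_cap_geometry(noiseless_image_preset):
    with pytest.raises(ValueError):
        sd.gen_nucleus_image(noiseless_image_preset.replace(cap_span=0.0), seed=1)
    with pytest.raises(ValueError):
        sd.gen_nucleus_image(noiseless_image_preset.replace(cap_span=7.0), seed=1)
    with pytest.raises(ValueError):
        sd.gen_nucleus_image(noiseless_image_preset.replace(cap_ratio=0.5), seed=1)


def test_uniform_rim_quantifies_flat(noiseless_image_preset):
    img = sd.gen_nucleus_image(noiseless_image_preset.replace(cap_ratio=1.0),
                               seed=5)
    quant = nq.cap_ratio(img, circle_theta=0.3)
    assert quant.Ic == pytest.approx(1.0, abs=1e-6)
    assert quant.Ir == 1.0


def test_cap_rim_trace_ratio_matches_generator(noiseless_image_preset):
    # cap intensity 3x the rest over a quarter-circle span: the in/out means
    # of the extracted rim trace recover the generating ratio
    preset = noiseless_image_preset.replace(cap_ratio=3.0, cap_span=math.pi / 2,
                                            background=0.0)
    img = sd.gen_nucleus_image(preset, seed=6)
    prof = nq.extract_rim_trace(img)
    angles = prof.truth["angles"]
    d = np.angle(np.exp(1j * (angles - img.truth["cap_theta"])))
    inside = np.abs(d) <= math.pi / 4 - 0.08  # clear of pixelated edges
    outside = np.abs(d) >= math.pi / 4 + 0.08
    ratio = prof.green[inside].mean() / prof.green[outside].mean()
    assert ratio == pytest.approx(3.0, rel=0.01)


# --- rim profiles -----------------------------------------------------------

def test_rim_profile_noiseless_enrichment_exact(noiseless_rim_preset):
    profiles = sd.gen_rim_profiles(noiseless_rim_preset.replace(enrichment=0.5),
                                   1, seed=7)
    _, enr = nq.align_and_average_profiles(profiles)
    assert enr == pytest.approx(50.0, abs=1e-9)


def test_rim_profile_zero_amplitude(noiseless_rim_preset):
    profiles = sd.gen_rim_profiles(noiseless_rim_preset.replace(enrichment=0.0),
                                   5, seed=8)
    _, enr = nq.align_and_average_profiles(profiles)
    assert enr == pytest.approx(0.0, abs=1e-9)


def test_rim_profile_sampling_and_truth(noiseless_rim_preset):
    profiles = sd.gen_rim_profiles(noiseless_rim_preset, 3, seed=9)
    for p in profiles:
        assert p.ds <= 0.065
        assert p.green.mean() == pytest.approx(1.0, abs=1e-9)
        assert p.red.max() == pytest.approx(1.0)
        assert p.truth["enrichment"] == 0.332
        assert p.peak_index == p.truth["peak_index"]


# --- FLIP / FRAP ------------------------------------------------------------

def test_flip_immobile_pool_gives_flat_trace(noiseless_flip_preset):
    tr, _ = sd.gen_flip_series(noiseless_flip_preset.replace(immobile_frac=1.0),
                               seed=10)
    assert np.allclose(tr.I, 100.0)


def test_flip_rate_inversion_matches_reported_times(noiseless_flip_preset):
    # the generating rates are analytic inversions t_q = ln(1/q)/k
    tr_a, tr_b = sd.gen_flip_series(noiseless_flip_preset, seed=11)
    k_a = noiseless_flip_preset["k_a"]
    assert math.log(10 / 7) / k_a == pytest.approx(82.0, abs=1e-9)
    # noiseless traces sampled exactly on the bleach schedule
    assert tr_a.t.size == 30 and tr_a.t[1] - tr_a.t[0] == 9.0
    assert np.allclose(tr_a.I, 100 * np.exp(-k_a * tr_a.t))
    assert tr_b.roi == "opposite"


@pytest.mark.parametrize("plateau,expected", [
    (100.0, -math.log(1 - 15 / 100) / 0.0325),
    (30.0, -math.log(1 - 15 / 30) / 0.0325),
])
def test_frap_closed_form_t15(plateau, expected):
    preset = get_preset("frap-stable-pore").replace(
        k_recovery=0.0325, plateau=plateau, noise_sd=0.0)
    tr = sd.gen_frap_series(preset, seed=12)
    from circlekeeper.photobleach_kinetics import fit_recovery
    fit = fit_recovery(tr)
    assert fit.t_q[0.15] == pytest.approx(expected, abs=0.1)


# --- tracks -----------------------------------------------------------------

def test_static_track_speed_zero():
    preset = get_preset("track-wt").replace(sigma_step=1e-12)
    tracks = sd.gen_tracks(preset, 3, seed=13)
    assert nq.cohort_speed(tracks) == pytest.approx(0.0, abs=1e-9)


def test_step_length_chi3_oracle():
    # 3-D Gaussian steps of per-axis SD sigma have mean length
    # sigma * E[chi_3] with E[chi_3] = sqrt(2) Gamma(2)/Gamma(3/2)
    sigma = 0.1
    preset = get_preset("track-wt").replace(sigma_step=sigma)
    tracks = sd.gen_tracks(preset, 200, seed=14)  # 200*60 = 12000 steps
    steps = np.concatenate([np.linalg.norm(np.diff(t.xyz, axis=0), axis=1)
                            for t in tracks])
    assert steps.mean() == pytest.approx(sigma * CHI3_MEAN, abs=0.002)
    assert sigma * CHI3_MEAN == pytest.approx(0.1596, abs=5e-4)


def test_confined_track_stays_inside_sphere():
    preset = get_preset("track-wt").replace(confine_radius=0.5)
    for tr in sd.gen_tracks(preset, 10, seed=15):
        assert np.linalg.norm(tr.xyz, axis=1).max() <= 0.5 + 1e-9
        assert tr.dt == 3.0 and tr.t.size == 61


# --- pedigrees and colonies -------------------------------------------------

def test_pedigree_no_propagation_all_daughters_lack_marker(wt):
    table = sd.gen_pedigree_table(wt.replace(p_prop=0.0), 500, seed=16)
    assert (~table["daughter_has_marker"]).all()


@pytest.mark.parametrize("k,p,expected,tol", [
    (24, 0.039, 100 * 0.961 ** 24, 2.0),   # ~38% of mothers keep every circle
    (1, 0.5, 50.0, 2.0),
    (24, 0.11, 100 * 0.89 ** 24, 1.0),
])
def test_pedigree_retention_closed_form(wt, k, p, expected, tol):
    from circlekeeper.retention_stats import pedigree_retention_frequency
    table = sd.gen_pedigree_table(wt.replace(p_prop=p, pedigree_k=k),
                                  10_000, seed=17)
    assert pedigree_retention_frequency(table) == pytest.approx(expected, abs=tol)


def test_pedigree_monte_carlo_convergence(wt):
    # MC error shrinks ~1/sqrt(n): the n=1e5 estimate must sit within a
    # 4-sigma binomial band around the closed form, tighter than at n=1e4
    from circlekeeper.retention_stats import pedigree_retention_frequency
    truth = 100 * 0.961 ** 24
    for n in (10_000, 100_000):
        table = sd.gen_pedigree_table(wt, n, seed=18)
        se = 100 * math.sqrt(0.385 * 0.615 / n)
        assert abs(pedigree_retention_frequency(table) - truth) < 4 * se


def test_sector_colonies_product_law(wt):
    from circlekeeper.retention_stats import half_sector_rate
    none = sd.gen_sector_colonies(wt.replace(p_excise=0.0), 1000, seed=19)
    assert half_sector_rate(none) == 0.0
    base = sd.gen_sector_colonies(wt.replace(p_excise=0.01, p_first_loss=0.5),
                                  100_000, seed=20)
    assert half_sector_rate(base) == pytest.approx(0.005, abs=0.0005)
    double = sd.gen_sector_colonies(wt.replace(p_excise=0.02, p_first_loss=0.5),
                                    100_000, seed=21)
    assert half_sector_rate(double) / half_sector_rate(base) == \
        pytest.approx(2.0, abs=0.1)


def test_division_records_match_preset_median():
    recs = sd.gen_division_records(get_preset("wt-loaded"), 2000, seed=22)
    pct = [nq.percent_to_mother(r) for r in recs]
    assert np.median(pct) == pytest.approx(78.0, abs=1.0)
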