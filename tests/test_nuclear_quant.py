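"""Image, profile, track and age-trend quantifiers against generator truth."""

import math

import numpy as np
import pytest

from circlekeeper import get_preset
from circlekeeper import nuclear_quant as nq
from circlekeeper import synthetic_data as sd
from circlekeeper.datatypes import DivisionRecord, NucleusImage, RimProfile


# --- integrated fluorescence ------------------------------------------------

def test_uniform_image_integrates_to_zero():
    img = NucleusImage(pixels=np.full((32, 32), 7.0), pixel_size=0.1,
                       truth={"radius_um": 1.0})
    roi = nq.nucleus_mask(img)
    assert nq.integrated_fluorescence(img, roi=roi) == pytest.approx(0.0)


def test_noiseless_total_matches_photon_bookkeeping(noiseless_image_preset):
    img = sd.gen_nucleus_image(noiseless_image_preset, seed=1)
    total = nq.integrated_fluorescence(
        img, roi=np.ones_like(img.pixels, dtype=bool),
        bg=img.truth["background"])
    assert total == pytest.approx(img.truth["rim_total"], abs=1e-6)


def test_loaded_unloaded_fold():
    loaded = [sd.gen_nucleus_image(get_preset("wt-loaded"), seed=100 + i)
              for i in range(50)]
    unloaded = [sd.gen_nucleus_image(get_preset("unloaded"), seed=300 + i)
                for i in range(50)]
    med_l = np.median([nq.integrated_fluorescence(i) for i in loaded])
    med_u = np.median([nq.integrated_fluorescence(i) for i in unloaded])
    assert med_l / med_u == pytest.approx(2.7, abs=0.3)


# --- cap quantification -----------------------------------------------------

def test_cap_cohort_recovers_preset_ratio():
    images = [sd.gen_nucleus_image(get_preset("wt-loaded"), seed=500 + i)
              for i in range(50)]
    df = nq.cap_ratio_cohort(images)
    assert df["Ir"].median() == pytest.approx(1.0, abs=1e-9)
    assert df["Ic"].mean() == pytest.approx(2.02, abs=0.15)


def test_cap_cohort_bud6_preset():
    images = [sd.gen_nucleus_image(get_preset("bud6-loaded"), seed=700 + i)
              for i in range(50)]
    df = nq.cap_ratio_cohort(images)
    assert df["Ic"].mean() == pytest.approx(2.29, abs=0.15)


def test_cap_ratio_invariant_to_intensity_rescaling(noiseless_image_preset):
    img = sd.gen_nucleus_image(noiseless_image_preset, seed=2)
    ref = nq.cap_ratio(img).Ic
    scaled = NucleusImage(pixels=img.pixels * 4.0, pixel_size=img.pixel_size,
                          truth=dict(img.truth,
                                     background=img.truth["background"] * 4.0))
    assert nq.cap_ratio(scaled).Ic == pytest.approx(ref, rel=1e-9)


def test_cap_region_must_touch_rim(noiseless_image_preset):
    img = sd.gen_nucleus_image(noiseless_image_preset, seed=3)
    with pytest.raises(ValueError):
        nq.cap_ratio(img, span=-1.0)


# --- division asymmetry -----------------------------------------------------

def test_equal_totals_split_fifty_fifty():
    rec = DivisionRecord(mother_total=10.0, bud_total=10.0)
    assert nq.percent_to_mother(rec) == 50.0


def test_mother_and_bud_percentages_sum_to_hundred():
    rng = np.random.default_rng(4)
    for _ in range(50):
        m, b = rng.uniform(0.1, 100, 2)
        fwd = nq.percent_to_mother(DivisionRecord(mother_total=m, bud_total=b))
        rev = nq.percent_to_mother(DivisionRecord(mother_total=b, bud_total=m))
        assert fwd + rev == pytest.approx(100.0, abs=1e-9)


@pytest.mark.parametrize("preset,median", [("wt-loaded", 78.0),
                                           ("unloaded", 63.0)])
def test_division_medians_match_presets(preset, median):
    recs = sd.gen_division_records(get_preset(preset), 50, seed=5)
    pct = [nq.percent_to_mother(r) for r in recs]
    assert np.median(pct) == pytest.approx(median, abs=3.0)


# --- rim traces and alignment ----------------------------------------------

def test_uniform_rim_trace_is_flat(noiseless_image_preset):
    img = sd.gen_nucleus_image(noiseless_image_preset.replace(cap_ratio=1.0),
                               seed=6)
    prof = nq.extract_rim_trace(img)
    assert prof.green.std() < 0.01
    assert prof.ds <= img.pixel_size / 2


def test_rim_trace_peak_at_plasmid_angle(noiseless_image_preset):
    img = sd.gen_nucleus_image(noiseless_image_preset, seed=7)
    prof = nq.extract_rim_trace(img)
    angles = prof.truth["angles"]
    target = img.truth["plasmid_theta"] % (2 * math.pi)
    peak_angle = angles[prof.peak_index]
    diff = abs(np.angle(np.exp(1j * (peak_angle - target))))
    assert diff <= 2 * (angles[1] - angles[0])


def test_flat_profiles_have_zero_enrichment():
    n = 256
    s = np.arange(n) * (2 * math.pi / n)
    red = np.exp(-np.minimum(np.arange(n), n - np.arange(n)) ** 2 / 20.0)
    profiles = [RimProfile(s=s, green=np.ones(n), red=red) for _ in range(3)]
    _, enr = nq.align_and_average_profiles(profiles)
    assert enr == pytest.approx(0.0, abs=1e-9)


def test_enrichment_recovers_wt_preset():
    profiles = sd.gen_rim_profiles(get_preset("rim-wt"), 50, seed=8)
    _, enr = nq.align_and_average_profiles(profiles)
    assert enr == pytest.approx(33.2, abs=3.0)


def test_enrichment_null_preset_near_zero():
    profiles = sd.gen_rim_profiles(get_preset("rim-null"), 50, seed=9)
    _, enr = nq.align_and_average_profiles(profiles)
    assert abs(enr) <= 5.0


def test_enrichment_invariant_to_green_rescaling(noiseless_rim_preset):
    profiles = sd.gen_rim_profiles(noiseless_rim_preset, 4, seed=10)
    _, ref = nq.align_and_average_profiles(profiles)
    scaled = [RimProfile(s=p.s, green=p.green * 11.0, red=p.red)
              for p in profiles]
    _, enr = nq.align_and_average_profiles(scaled)
    assert enr == pytest.approx(ref, rel=1e-9)


def test_profiles_must_share_grid():
    s1 = np.arange(256) * 0.02
    s2 = np.arange(128) * 0.04
    p1 = RimProfile(s=s1, green=np.ones(256), red=np.ones(256))
    p2 = RimProfile(s=s2, green=np.ones(128), red=np.ones(128))
    with pytest.raises(ValueError):
        nq.align_and_average_profiles([p1, p2])


# --- rim proximity ----------------------------------------------------------

def test_rim_proximity_trivial_cases():
    assert nq.classify_rim_proximity((1.0, 0.0)) == "at_rim"
    assert nq.classify_rim_proximity((0.0, 0.0)) == "resolvable"


def test_rim_proximity_cohort_round_trip(wt):
    pos = sd.gen_plasmid_positions(get_preset("wt-loaded"), 2000, seed=11)
    frac = np.mean([nq.classify_rim_proximity((r.x_um, r.y_um)) == "resolvable"
                    for r in pos.itertuples()]) * 100
    assert frac == pytest.approx(15.0, abs=3.0)


def test_resolvable_fraction_monotone_in_threshold():
    pos = sd.gen_plasmid_positions(get_preset("wt-loaded"), 500, seed=12)
    fracs = []
    for thr in (0.05, 0.15, 0.25, 0.5):
        fracs.append(np.mean([
            nq.classify_rim_proximity((r.x_um, r.y_um), threshold_um=thr)
            == "resolvable" for r in pos.itertuples()]))
    assert all(a >= b for a, b in zip(fracs, fracs[1:]))


# --- track speed ------------------------------------------------------------

@pytest.mark.parametrize("preset,speed", [("track-wt", 0.05),
                                          ("track-gcn5", 0.09)])
def test_cohort_speed_matches_preset(preset, speed):
    tracks = sd.gen_tracks(get_preset(preset), 50, seed=13)
    assert nq.cohort_speed(tracks) == pytest.approx(speed, abs=0.01)


# --- age trends -------------------------------------------------------------

def test_constant_age_trend_degenerates_to_flat_fit():
    ages = np.repeat(np.arange(1, 21), 2)
    res = nq.age_trend(list(zip(ages, np.full(40, 64.0))))
    assert res.params["plateau"] == 64.0
    assert res.params["k"] == pytest.approx(0.0, abs=1e-9)


def test_association_round_trip_recovers_plateau():
    # asymmetry rising from 56% toward 78% with age, as in microfluidic
    # NPC-retention series
    rng = np.random.default_rng(14)
    ages = rng.uniform(1, 40, 200)
    vals = 78 - (78 - 56) * np.exp(-0.12 * ages) + rng.normal(0, 2.5, 200)
    res = nq.age_trend(np.column_stack([ages, vals]))
    assert 74 <= res.params["plateau"] <= 82
    assert len(res.dots) == 20
    assert "plateau" in res.summary()


def test_exponential_round_trip_recovers_rate():
    rng = np.random.default_rng(15)
    ages = rng.uniform(1, 35, 150)
    lam = 0.08
    vals = 50 * np.exp(lam * ages) * rng.normal(1.0, 0.05, 150)
    res = nq.age_trend(np.column_stack([ages, vals]), model="exponential")
    assert res.params["rate"] == pytest.approx(lam, rel=0.1)
    # renormalised by the fitted intercept
    assert res.normalized_values is not None


def test_age_trend_requires_enough_span():
    with pytest.raises(ValueError):
        nq.age_trend([(1, 1.0)] * 25)  # no age span
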