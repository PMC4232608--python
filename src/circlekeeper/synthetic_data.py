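"""Synthetic-data generators.

Every input the analysis pipeline consumes can be generated here with the
statistical structure the analysis assumes: telophase segregation tallies
with independent per-plasmid propagation, nucleus images drawn as blurred
rims with an NPC cap under Poisson + Gaussian noise, rim-intensity profiles
with a plasmid-centred enrichment bump, two-pool FLIP decays and one-phase
FRAP recoveries, confined 3-D diffusion tracks, mother pedigrees, sectored
colonies, and telophase division records.

All generators are deterministic given ``(preset, seed)``; randomness flows
from one ``numpy`` Generator created per call, never from global state.
Ground truth is recorded alongside every synthetic object so that the
quantifiers can be validated by round-trip.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import (DivisionRecord, FluorTrace, GeneratorPreset,
                        NucleusImage, RimProfile, SegregationCounts, Track)
from .nuclear_quant import window_mask


def _rng(preset: GeneratorPreset, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(preset.seed if seed is None else seed)


# ---------------------------------------------------------------------------
# Telophase segregation tallies
# ---------------------------------------------------------------------------

def gen_segregation_counts(preset: GeneratorPreset, n_cells: int,
                           seed: int | None = None) -> SegregationCounts:
    """Tally of telophase cells with 1/2/4 plasmids and the percentage of
    each category retaining all plasmids in the mother.

    Each of a cell's ``m`` plasmids propagates to the bud independently with
    probability ``p_prop``; the cell "retains all" iff none propagate.
    Categories with zero cells get an undefined (``None``) percentage.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = _rng(preset, seed)
    p = float(preset["p_prop"])
    mix = np.asarray(preset.get("count_mix", (0.61, 0.33, 0.06)), dtype=float)
    counts = rng.multinomial(n_cells, mix)
    pct = []
    for m, n_cat in zip((1, 2, 4), counts):
        if n_cat == 0:
            pct.append(None)
            continue
        propagated = rng.binomial(m, p, size=n_cat)
        pct.append(100.0 * float(np.count_nonzero(propagated == 0)) / n_cat)
    return SegregationCounts(x=int(counts[0]), y=int(counts[1]), z=int(counts[2]),
                             a=pct[0], b=pct[1], c=pct[2])


# ---------------------------------------------------------------------------
# Nucleus images
# ---------------------------------------------------------------------------

def _rim_field(preset: GeneratorPreset, loaded: bool, cap_theta: float,
               center: tuple[float, float]) -> tuple[np.ndarray, dict]:
    """Noiseless rim component (counts per pixel) and its bookkeeping."""
    h, w = preset.get("shape", (64, 64))
    px = float(preset["pixel_size"])
    radius = float(preset["rim_radius"])
    blur = float(preset.get("rim_blur_sd", 0.25))
    cap_ratio = float(preset.get("cap_ratio", 1.0)) if loaded else 1.0
    span = float(preset.get("cap_span", math.pi / 2))
    if not 0.0 < span < 2.0 * math.pi:
        raise ValueError("cap span must lie in (0, 2*pi)")
    if cap_ratio < 1.0:
        raise ValueError("cap_ratio must be >= 1")
    if radius >= 0.5 * min(h, w) * px:
        raise ValueError("rim radius must be smaller than half the image extent")

    yy, xx = np.mgrid[0:h, 0:w]
    dx = (xx - center[1]) * px
    dy = (yy - center[0]) * px
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    radial = np.exp(-((r - radius) ** 2) / (2.0 * blur ** 2))
    dtheta = np.angle(np.exp(1j * (theta - cap_theta)))
    angular = np.where(np.abs(dtheta) <= span / 2.0, cap_ratio, 1.0)
    rim = radial * angular
    rim *= float(preset["photons"]) / rim.sum()
    truth = dict(center=center, radius_um=radius, cap_theta=cap_theta,
                 cap_span=span, cap_ratio=cap_ratio, rim_blur_sd=blur,
                 rim_total=float(rim.sum()), loaded=loaded)
    return rim, truth


def gen_nucleus_image(preset: GeneratorPreset, loaded: bool | None = None,
                      seed: int | None = None) -> NucleusImage:
    """Synthetic nucleus: a Gaussian-blurred bright rim, with an NPC cap of
    intensity ``cap_ratio`` x the residual rim (and a plasmid focus in the
    red channel at the cap centre) when ``loaded``.

    Noise model: Poisson shot noise scaled by ``gain``, then additive
    Gaussian read noise of SD ``read_noise_sd``; either is disabled by
    setting it to 0.  The ``truth`` block records every generating value.
    """
    rng = _rng(preset, seed)
    if loaded is None:
        loaded = bool(preset.get("loaded", False))
    h, w = preset.get("shape", (64, 64))
    px = float(preset["pixel_size"])
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    cap_theta = float(rng.uniform(-math.pi, math.pi))
    rim, truth = _rim_field(preset, loaded, cap_theta, center)
    bg = float(preset.get("background", 0.0))
    clean = rim + bg

    gain = float(preset.get("gain", 0.0))
    read_sd = float(preset.get("read_noise_sd", 0.0))
    pixels = clean.copy()
    if gain > 0:
        pixels = rng.poisson(clean / gain).astype(float) * gain
    if read_sd > 0:
        pixels = pixels + rng.normal(0.0, read_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, None)

    red = None
    if loaded:
        radius = truth["radius_um"]
        py = center[0] + radius / px * math.sin(cap_theta)
        pxx = center[1] + radius / px * math.cos(cap_theta)
        yy, xx = np.mgrid[0:h, 0:w]
        focus_sd = 0.15 / px  # ~diffraction-limited focus, in pixels
        red = 200.0 * np.exp(-((yy - py) ** 2 + (xx - pxx) ** 2) / (2 * focus_sd ** 2))
        if read_sd > 0:
            red = np.clip(red + rng.normal(0.0, read_sd, size=red.shape), 0.0, None)
        truth["plasmid_theta"] = cap_theta
        truth["plasmid_xy"] = (float(py), float(pxx))
    truth["background"] = bg
    truth["pixel_size"] = px
    return NucleusImage(pixels=pixels, pixel_size=px, truth=truth, red=red)


# ---------------------------------------------------------------------------
# Rim-intensity profiles
# ---------------------------------------------------------------------------

def _bump_amplitude(shape: np.ndarray, mask_in: np.ndarray, target: float) -> float:
    """Bump amplitude giving window enrichment exactly ``target`` on the grid.

    With green = 1 + A*shape, the quantified enrichment is
    (1 + A*m_in) / (1 + A*m_out) - 1; solve for A.
    """
    m_in = shape[mask_in].mean()
    m_out = shape[~mask_in].mean()
    denom = m_in - (1.0 + target) * m_out
    if denom <= 0:
        raise ValueError("enrichment target unreachable for this bump shape")
    return target / denom


def gen_rim_profiles(preset: GeneratorPreset, n_cells: int,
                     seed: int | None = None) -> list[RimProfile]:
    """Rim-intensity profiles: green = baseline + Gaussian bump centred at
    the plasmid position + correlated noise; red = peak at the plasmid.

    The preset's ``enrichment`` parameter is the *target* fractional window
    enrichment; the bump amplitude is solved so that a noiseless profile
    quantifies to exactly that value (stored per profile as ground truth).
    """
    rng = _rng(preset, seed)
    radius = float(preset.get("rim_radius", 1.0))
    n = int(preset.get("n_samples", 256))
    ds = 2.0 * math.pi * radius / n
    if ds > 0.065:
        raise ValueError("arc sampling step must be <= 65 nm")
    s = np.arange(n) * ds
    window = float(preset.get("window_um", 0.130))
    bump_sd = float(preset.get("bump_sd", 0.060))
    target = float(preset.get("enrichment", 0.0))
    noise_sd = float(preset.get("noise_sd", 0.0))
    corr = float(preset.get("noise_corr_um", 0.05))
    red_sd = float(preset.get("red_peak_sd", 0.040))
    red_noise = float(preset.get("red_noise_sd", 0.0))

    # circular distance of every sample from the origin sample
    d0 = np.minimum(np.arange(n), n - np.arange(n)) * ds
    shape0 = np.exp(-d0 ** 2 / (2.0 * bump_sd ** 2))
    mask_in0 = window_mask(n, ds, window)
    amp = 0.0 if target == 0.0 else _bump_amplitude(shape0, mask_in0, target)

    profiles = []
    for _ in range(n_cells):
        peak = int(rng.integers(0, n))
        shape = np.roll(shape0, peak)
        green = 1.0 + amp * shape
        if noise_sd > 0:
            raw = rng.normal(0.0, 1.0, size=n)
            sm = ndimage.gaussian_filter1d(raw, sigma=corr / ds, mode="wrap")
            sm *= noise_sd / sm.std()
            green = np.clip(green + sm, 1e-6, None)
        red = 0.05 + np.roll(np.exp(-d0 ** 2 / (2.0 * red_sd ** 2)), peak)
        if red_noise > 0:
            red = np.clip(red + rng.normal(0.0, red_noise, size=n), 0.0, None)
        profiles.append(RimProfile(
            s=s, green=green, red=red,
            truth=dict(enrichment=target, amplitude=amp, peak_index=peak,
                       window_um=window)))
    return profiles


# ---------------------------------------------------------------------------
# FLIP / FRAP traces
# ---------------------------------------------------------------------------

def _two_pool_decay(t, k, immobile_frac):
    if math.isinf(k):
        return np.where(t > 0, 100.0 * immobile_frac, 100.0)
    return 100.0 * (immobile_frac + (1.0 - immobile_frac) * np.exp(-k * t))


def gen_flip_series(preset: GeneratorPreset,
                    seed: int | None = None) -> tuple[FluorTrace, FluorTrace]:
    """Pair of FLIP traces sampled on the repeated-bleach schedule.

    Each ROI decays as a two-pool model: the mobile fraction decays as
    ``exp(-k t)`` and the immobile fraction does not.  The pair carries the
    preset's two ROIs (circle-adjacent vs opposite, or mother vs bud) with
    their own rates ``k_a`` / ``k_b``.
    """
    rng = _rng(preset, seed)
    dt = float(preset.get("dt", 9.0))
    npts = int(preset.get("n_points", 30))
    t = dt * np.arange(npts)
    noise_sd = float(preset.get("noise_sd", 0.0))
    immobile = float(preset.get("immobile_frac", 0.0))
    traces = []
    for key_k, key_roi, default_roi in (("k_a", "roi_a", "circle-adjacent"),
                                        ("k_b", "roi_b", "opposite")):
        k = float(preset.get(key_k, preset.get("k_decay")))
        if k <= 0:
            raise ValueError("decay rate must be strictly positive")
        I = _two_pool_decay(t, k, immobile)
        if noise_sd > 0:
            I = np.clip(I + rng.normal(0.0, noise_sd, size=npts), 0.0, None)
        traces.append(FluorTrace(t=t, I=I, roi=str(preset.get(key_roi, default_roi)),
                                 bleach_times=t, normalized=False))
    return traces[0], traces[1]


def gen_frap_series(preset: GeneratorPreset, seed: int | None = None) -> FluorTrace:
    """FRAP recovery after bleaching the bud compartment:
    ``I(t) = plateau * (1 - exp(-k t))`` plus optional Gaussian noise."""
    rng = _rng(preset, seed)
    plateau = float(preset.get("plateau", 100.0))
    if not 0.0 < plateau <= 100.0:
        raise ValueError("plateau must lie in (0, 100]")
    k = float(preset["k_recovery"])
    dt = float(preset.get("dt", 3.0))
    npts = int(preset.get("n_points", 61))
    t = dt * np.arange(npts)
    I = plateau * (1.0 - np.exp(-k * t))
    noise_sd = float(preset.get("noise_sd", 0.0))
    if noise_sd > 0:
        I = np.clip(I + rng.normal(0.0, noise_sd, size=npts), 0.0, None)
    I[0] = 0.0  # fluorescence is set to zero at the bleach
    return FluorTrace(t=t, I=I, roi="bud", bleach_times=np.array([0.0]),
                      normalized=True)


# ---------------------------------------------------------------------------
# 3-D plasmid tracks
# ---------------------------------------------------------------------------

def gen_tracks(preset: GeneratorPreset, n_tracks: int,
               seed: int | None = None) -> list[Track]:
    """Confined 3-D random walks: per-axis Gaussian steps of SD
    ``sigma_step`` every ``dt`` seconds, reflected at ``confine_radius``
    (unconfined when the radius is absent or infinite)."""
    rng = _rng(preset, seed)
    sigma = float(preset["sigma_step"])
    if sigma < 0:
        raise ValueError("sigma_step must be non-negative")
    dt = float(preset.get("dt", 3.0))
    npts = int(preset.get("n_points", 61))
    radius = preset.get("confine_radius", None)
    radius = float(radius) if radius is not None else math.inf
    t = dt * np.arange(npts)
    tracks = []
    for _ in range(n_tracks):
        steps = rng.normal(0.0, sigma, size=(npts - 1, 3)) if sigma > 0 else \
            np.zeros((npts - 1, 3))
        pos = np.zeros((npts, 3))
        for i, step in enumerate(steps, start=1):
            nxt = pos[i - 1] + step
            r = np.linalg.norm(nxt)
            if r > radius:                       # mirror across the sphere
                nxt = nxt * (2.0 * radius - r) / r
            pos[i] = nxt
        tracks.append(Track(t=t, xyz=pos))
    return tracks


# ---------------------------------------------------------------------------
# Pedigrees, colonies, division records, plasmid positions
# ---------------------------------------------------------------------------

def gen_pedigree_table(preset: GeneratorPreset, n_mothers: int,
                       seed: int | None = None) -> pd.DataFrame:
    """Mother/daughter marker pedigree: a mother carrying ``pedigree_k``
    circles passes the marker to her daughter iff at least one circle
    propagates, i.e. with probability ``1 - (1 - p_prop)**k``."""
    rng = _rng(preset, seed)
    k = int(preset.get("pedigree_k", 24))
    p = float(preset["p_prop"])
    p_marker = 1.0 - (1.0 - p) ** k
    has_marker = rng.random(n_mothers) < p_marker
    return pd.DataFrame({
        "mother_id": np.arange(n_mothers),
        "mother_circle_count": np.full(n_mothers, k),
        "daughter_has_marker": has_marker,
    })


def gen_sector_colonies(preset: GeneratorPreset, n_colonies: int,
                        seed: int | None = None) -> pd.DataFrame:
    """Colony sectoring: a colony is half-sectored iff marker excision
    happens before the first division (prob ``p_excise``) AND the excised
    circle is lost from one first-division lineage (prob ``p_first_loss``).
    Excision without first-division loss yields an 'other' sector class."""
    rng = _rng(preset, seed)
    p_ex = float(preset.get("p_excise", 0.0))
    p_loss = float(preset.get("p_first_loss", 0.5))
    excised = rng.random(n_colonies) < p_ex
    first_loss = rng.random(n_colonies) < p_loss
    cls = np.where(excised & first_loss, "half",
                   np.where(excised, "other", "none"))
    return pd.DataFrame({"colony_id": np.arange(n_colonies), "sector_class": cls})


def gen_division_records(preset: GeneratorPreset, n_records: int,
                         seed: int | None = None) -> list[DivisionRecord]:
    """Telophase mother/bud integrated-fluorescence pairs.

    The mother share is drawn Normal(``pct_mother_median``,
    ``pct_mother_sd``) clipped to (0, 1); the total is drawn
    Normal(``division_total``, ``division_total_sd``).
    """
    rng = _rng(preset, seed)
    med = float(preset.get("pct_mother_median", 0.5))
    sd = float(preset.get("pct_mother_sd", 0.06))
    total_mu = float(preset.get("division_total", 1000.0))
    total_sd = float(preset.get("division_total_sd", 0.0))
    records = []
    for i in range(n_records):
        share = float(np.clip(rng.normal(med, sd), 1e-3, 1.0 - 1e-3))
        total = max(float(rng.normal(total_mu, total_sd)), 1.0)
        area = max(float(rng.normal(4.0, 0.5)), 0.5)
        records.append(DivisionRecord(
            mother_total=share * total, bud_total=(1.0 - share) * total,
            mother_area=area * share, bud_area=area * (1.0 - share),
            age=i, label=preset.name))
    return records


def gen_plasmid_positions(preset: GeneratorPreset, n_cells: int,
                          seed: int | None = None,
                          threshold_um: float = 0.25) -> pd.DataFrame:
    """Plasmid focus positions for rim-proximity classification: a fraction
    ``p_interior`` sits well inside the nucleus (> threshold from the rim),
    the rest on the rim circle with sub-threshold jitter."""
    rng = _rng(preset, seed)
    radius = float(preset.get("rim_radius", 1.0))
    p_int = float(preset.get("p_interior", 0.15))
    interior = rng.random(n_cells) < p_int
    rows = []
    for is_int in interior:
        theta = rng.uniform(-math.pi, math.pi)
        if is_int:
            r = rng.uniform(0.0, max(radius - 2.0 * threshold_um, 0.0))
        else:
            r = radius + rng.uniform(-0.4, 0.4) * threshold_um
        rows.append((r * math.cos(theta), r * math.sin(theta), bool(is_int)))
    return pd.DataFrame(rows, columns=["x_um", "y_um", "interior_truth"])
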