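"""Quantification of nucleus images, rim profiles, divisions, tracks and
age series.

The operations mirror how the underlying microscopy measurements are made:
integrated density with background subtraction, mean gray values in the
circle-adjacent versus residual rim normalised to the cohort median,
percent-of-total fluorescence segregated to the mother, rim traces aligned
on the plasmid peak, per-interval 3-D step speeds, and age trends fitted
with one-phase association or exponential models.

Coordinates are 0-based with pixel centres at integer positions; ROIs are
boolean pixel masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .datatypes import CapQuant, DivisionRecord, NucleusImage, RimProfile, Track


# ---------------------------------------------------------------------------
# masks and integrated fluorescence
# ---------------------------------------------------------------------------

def _polar(image: NucleusImage):
    h, w = image.pixels.shape
    cy, cx = image.truth.get("center", ((h - 1) / 2.0, (w - 1) / 2.0))
    yy, xx = np.mgrid[0:h, 0:w]
    dx = (xx - cx) * image.pixel_size
    dy = (yy - cy) * image.pixel_size
    return np.hypot(dx, dy), np.arctan2(dy, dx)


def rim_mask(image: NucleusImage, width_um: float | None = None) -> np.ndarray:
    """Annulus of pixels within ``width_um`` of the rim radius (default:
    twice the rim blur SD)."""
    r, _ = _polar(image)
    radius = image.truth["radius_um"]
    if width_um is None:
        width_um = 2.0 * image.truth.get("rim_blur_sd", 0.25)
    return np.abs(r - radius) <= width_um


def nucleus_mask(image: NucleusImage, margin_um: float = 1.0) -> np.ndarray:
    """Disk covering the nucleus plus a safety margin for the blurred rim."""
    r, _ = _polar(image)
    return r <= image.truth["radius_um"] + margin_um


def background_mask(image: NucleusImage, margin_um: float = 1.0) -> np.ndarray:
    return ~nucleus_mask(image, margin_um)


def integrated_fluorescence(image: NucleusImage, roi: np.ndarray | None = None,
                            bg: np.ndarray | float | None = None) -> float:
    """Integrated density over ``roi`` minus the background estimate times
    the ROI area.  ``bg`` is a background pixel mask or a known per-pixel
    level; negatives are reported as-is, never clipped."""
    pixels = image.pixels
    if roi is None:
        roi = nucleus_mask(image)
    total = float(pixels[roi].sum())
    if bg is None:
        bg_level = float(pixels[background_mask(image)].mean())
    elif np.isscalar(bg):
        bg_level = float(bg)
    else:
        bg_level = float(pixels[np.asarray(bg, dtype=bool)].mean())
    return total - bg_level * int(np.count_nonzero(roi))


# ---------------------------------------------------------------------------
# cap quantification
# ---------------------------------------------------------------------------

def _cap_sector_masks(image: NucleusImage, circle_theta: float | None = None,
                      span: float | None = None):
    r, theta = _polar(image)
    rim = rim_mask(image)
    if circle_theta is None:
        circle_theta = image.truth.get("plasmid_theta", image.truth.get("cap_theta"))
    if circle_theta is None:
        raise ValueError("no circle position: pass circle_theta or provide truth")
    if span is None:
        span = image.truth.get("cap_span", math.pi / 2)
    dtheta = np.angle(np.exp(1j * (theta - circle_theta)))
    cap = rim & (np.abs(dtheta) <= span / 2.0)
    opposite = rim & (np.abs(np.angle(np.exp(1j * (theta - circle_theta - math.pi))))
                      <= span / 2.0)
    residual = rim & ~cap
    if not cap.any():
        raise ValueError("circle region does not intersect the rim annulus")
    return cap, residual, opposite


def cap_ratio(image: NucleusImage, circle_theta: float | None = None,
              span: float | None = None, bg: float | None = None) -> CapQuant:
    """Mean gray value of the circle-adjacent rim (Ic), the residual rim
    (Ir) and the circle-opposite sector (Io), background-subtracted and
    normalised by this cell's Ir (use :func:`cap_ratio_cohort` for the
    cohort-median normalisation)."""
    cap, residual, opposite = _cap_sector_masks(image, circle_theta, span)
    if bg is None:
        bg = float(image.pixels[background_mask(image)].mean())
    ic = float(image.pixels[cap].mean()) - bg
    ir = float(image.pixels[residual].mean()) - bg
    io = float(image.pixels[opposite].mean()) - bg
    if ir <= 0:
        raise ValueError("residual rim intensity is not positive")
    return CapQuant(Ic=ic / ir, Ir=1.0, Io=io / ir)


def cap_ratio_cohort(images: list[NucleusImage]) -> pd.DataFrame:
    """Per-cell Ic/Ir/Io normalised by the *cohort median* of the raw
    residual-rim intensity, so that median(Ir) = 1 across the cohort."""
    raw = []
    for img in images:
        cap, residual, opposite = _cap_sector_masks(img)
        bg = float(img.pixels[background_mask(img)].mean())
        raw.append((float(img.pixels[cap].mean()) - bg,
                    float(img.pixels[residual].mean()) - bg,
                    float(img.pixels[opposite].mean()) - bg))
    df = pd.DataFrame(raw, columns=["Ic", "Ir", "Io"])
    norm = float(df["Ir"].median())
    if norm <= 0:
        raise ValueError("cohort median residual-rim intensity is not positive")
    return df / norm


# ---------------------------------------------------------------------------
# division asymmetry
# ---------------------------------------------------------------------------

def percent_to_mother(record: DivisionRecord) -> float:
    """Percentage of the total (mother + bud) fluorescence retained by the
    mother; the mother and bud percentages sum to 100 exactly."""
    total = record.mother_total + record.bud_total
    if total <= 0:
        raise ValueError("total fluorescence must be positive")
    return 100.0 * record.mother_total / total


# ---------------------------------------------------------------------------
# rim traces and alignment
# ---------------------------------------------------------------------------

def extract_rim_trace(image: NucleusImage, center: tuple[float, float] | None = None,
                      radius_um: float | None = None) -> RimProfile:
    """Bilinear sampling of green (and red) intensity along the rim circle;
    arc step at most half a pixel."""
    h, w = image.pixels.shape
    if center is None:
        center = image.truth.get("center", ((h - 1) / 2.0, (w - 1) / 2.0))
    if radius_um is None:
        radius_um = image.truth["radius_um"]
    circumference = 2.0 * math.pi * radius_um
    n = int(math.ceil(circumference / (image.pixel_size / 2.0)))
    angles = 2.0 * math.pi * np.arange(n) / n
    r_px = radius_um / image.pixel_size
    ys = center[0] + r_px * np.sin(angles)
    xs = center[1] + r_px * np.cos(angles)
    green = ndimage.map_coordinates(image.pixels, [ys, xs], order=1)
    if image.red is not None:
        red = ndimage.map_coordinates(image.red, [ys, xs], order=1)
    else:
        red = np.zeros(n)
    s = angles * radius_um
    return RimProfile(s=s, green=green, red=red,
                      truth=dict(angles=angles, radius_um=radius_um))


def window_mask(n: int, ds: float, window_um: float) -> np.ndarray:
    """Samples within ``window_um`` of the origin on a circular arc grid of
    ``n`` samples spaced ``ds``.  Shared by generator and quantifier so the
    noiseless round-trip is exact."""
    d = np.minimum(np.arange(n), n - np.arange(n)) * ds
    return d <= window_um + 1e-12


def align_and_average_profiles(profiles: list[RimProfile],
                               window_nm: float = 130.0,
                               baseline: str = "outside"):
    """Circularly shift each green profile so its red peak maps to the
    origin, average, and compute the percent enrichment of the mean green
    signal within +/- ``window_nm`` of the peak.

    ``baseline='outside'`` compares against the mean outside the window
    (default); ``baseline='whole'`` against the whole-trace mean.
    Returns ``(mean_profile, enrichment_percent)``.
    """
    if len(profiles) < 1:
        raise ValueError("need at least one profile")
    n = profiles[0].green.size
    ds = profiles[0].ds
    for p in profiles:
        if p.green.size != n or not math.isclose(p.ds, ds, rel_tol=1e-9):
            raise ValueError("profiles must share one arc grid")
    stack = np.stack([np.roll(p.green, -p.peak_index) for p in profiles])
    mean_profile = stack.mean(axis=0)
    mask = window_mask(n, ds, window_nm * 1e-3)
    mean_in = float(mean_profile[mask].mean())
    if baseline == "outside":
        ref = float(mean_profile[~mask].mean())
    elif baseline == "whole":
        ref = float(mean_profile.mean())
    else:
        raise ValueError("baseline must be 'outside' or 'whole'")
    enrichment = 100.0 * (mean_in / ref - 1.0)
    return mean_profile, enrichment


# ---------------------------------------------------------------------------
# rim proximity and track speed
# ---------------------------------------------------------------------------

def classify_rim_proximity(pos_um, center_um=(0.0, 0.0), radius_um: float = 1.0,
                           threshold_um: float = 0.25) -> str:
    """'resolvable' iff the radial distance of the focus from the rim circle
    exceeds the resolution threshold, else 'at_rim'."""
    pos = np.asarray(pos_um, dtype=float) - np.asarray(center_um, dtype=float)
    dist = abs(float(np.linalg.norm(pos)) - radius_um)
    return "resolvable" if dist > threshold_um else "at_rim"


def track_speed(track: Track) -> float:
    """Mean 3-D step length per interval divided by the interval (um/s)."""
    steps = np.linalg.norm(np.diff(track.xyz, axis=0), axis=1)
    if steps.size == 0:
        return 0.0
    return float(steps.mean() / track.dt)


def cohort_speed(tracks: list[Track]) -> float:
    """Per-track mean speed, then the cohort mean."""
    return float(np.mean([track_speed(tr) for tr in tracks]))


# ---------------------------------------------------------------------------
# age trends
# ---------------------------------------------------------------------------

@dataclass
class AgeTrendResults:
    """Fit of an age trend, with the grouped display dots."""

    model: str
    params: dict
    dots: pd.DataFrame              # mean age, mean value, sd per group of 10
    raw: pd.DataFrame
    residual_norm: float
    normalized_values: np.ndarray | None = None

    def predict(self, age):
        age = np.asarray(age, dtype=float)
        p = self.params
        if self.model == "one_phase_association":
            return p["y0"] + (p["plateau"] - p["y0"]) * (1.0 - np.exp(-p["k"] * age))
        return p["y0"] * np.exp(p["rate"] * age)

    def summary(self) -> str:
        lines = [f"Age-trend fit: {self.model}", "-" * 34]
        for k, v in self.params.items():
            lines.append(f"{k:>10s}: {v:12.6g}")
        lines.append(f"{'resid':>10s}: {self.residual_norm:12.6g}")
        lines.append(f"{'n':>10s}: {len(self.raw):12d}")
        return "\n".join(lines)


class AgeTrendModel:
    """One-phase association or exponential model of a (age, value) cloud.

    Grouped dots are means/SDs of 10 consecutive age-sorted points; the fit
    is done on the raw points.  For the exponential model the values are
    additionally renormalised by the fitted intercept.
    """

    def __init__(self, age, value, model: str = "one_phase_association"):
        age = np.asarray(age, dtype=float)
        value = np.asarray(value, dtype=float)
        if age.size != value.size:
            raise ValueError("age and value must have equal length")
        if age.size < 20 or (age.max() - age.min()) < 10:
            raise ValueError("need >= 20 points spanning >= 10 generations")
        if model not in ("one_phase_association", "exponential"):
            raise ValueError(f"unknown model {model!r}")
        order = np.argsort(age, kind="stable")
        self.age, self.value = age[order], value[order]
        self.model = model

    def _dots(self, group: int = 10) -> pd.DataFrame:
        rows = []
        for i in range(0, self.age.size - group + 1, group):
            a = self.age[i:i + group]
            v = self.value[i:i + group]
            rows.append((a.mean(), v.mean(), v.std(ddof=1)))
        return pd.DataFrame(rows, columns=["age", "value", "sd"])

    def fit(self) -> AgeTrendResults:
        a, v = self.age, self.value
        raw = pd.DataFrame({"age": a, "value": v})
        dots = self._dots()
        if self.model == "one_phase_association":
            if np.std(v) < 1e-12:  # degenerate flat cloud: plateau at the constant
                params = {"y0": float(v[0]), "plateau": float(v[0]), "k": 0.0}
                return AgeTrendResults(self.model, params, dots, raw, 0.0)

            def f(x, y0, plateau, k):
                return y0 + (plateau - y0) * (1.0 - np.exp(-k * x))

            p0 = (float(v[:5].mean()), float(v[-5:].mean()), 0.1)
            popt, _ = optimize.curve_fit(f, a, v, p0=p0, maxfev=10000,
                                         bounds=([-np.inf, -np.inf, 0.0],
                                                 [np.inf, np.inf, np.inf]))
            params = {"y0": float(popt[0]), "plateau": float(popt[1]),
                      "k": float(popt[2])}
            resid = float(np.linalg.norm(v - f(a, *popt)))
            return AgeTrendResults(self.model, params, dots, raw, resid)

        def g(x, y0, rate):
            return y0 * np.exp(rate * x)

        p0 = (max(float(v[:5].mean()), 1e-9), 0.05)
        popt, _ = optimize.curve_fit(g, a, v, p0=p0, maxfev=10000)
        params = {"y0": float(popt[0]), "rate": float(popt[1])}
        resid = float(np.linalg.norm(v - g(a, *popt)))
        return AgeTrendResults(self.model, params, dots, raw, resid,
                               normalized_values=v / params["y0"])


def age_trend(pairs, model: str = "one_phase_association") -> AgeTrendResults:
    """Fit an age trend from (age, value) pairs (iterable or DataFrame)."""
    if isinstance(pairs, pd.DataFrame):
        age, value = pairs.iloc[:, 0], pairs.iloc[:, 1]
    else:
        arr = np.asarray(list(pairs), dtype=float)
        age, value = arr[:, 0], arr[:, 1]
    return AgeTrendModel(age, value, model=model).fit()
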