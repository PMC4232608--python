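"""Shared data containers for the circle-retention toolkit.

These are deliberately thin: arrays live in numpy, tables in pandas, and the
classes below only enforce the invariants that the quantifiers rely on
(normalisation conventions, monotone time bases, non-negative intensities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GeneratorPreset:
    """Named bundle of generator parameters.

    ``params`` maps parameter names to numbers; probabilities must lie in
    [0, 1], mixture proportions must sum to one, and rates/lengths must be
    strictly positive.  ``seed`` is the default random seed used when a
    generator is called without an explicit one.
    """

    name: str
    params: Mapping[str, object]
    seed: int = 0

    _PROBABILITIES = (
        "p_prop", "immobile_frac", "rho_retain", "f_form_prob", "f_form",
        "p_excise", "p_first_loss", "p_interior", "s0",
    )

    def __post_init__(self):
        for key in self._PROBABILITIES:
            if key in self.params:
                v = float(self.params[key])
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{self.name}: {key}={v} outside [0, 1]")
        if "count_mix" in self.params:
            mix = np.asarray(self.params["count_mix"], dtype=float)
            if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: count_mix must be non-negative and sum to 1")
        for key in ("k_decay", "k_adjacent", "k_opposite", "k_mother", "k_bud",
                    "k_recovery", "sigma_step", "dt", "pixel_size", "rim_radius"):
            if key in self.params and float(self.params[key]) <= 0:
                raise ValueError(f"{self.name}: {key} must be strictly positive")

    def get(self, key, default=None):
        return self.params.get(key, default)

    def __getitem__(self, key):
        return self.params[key]

    def replace(self, **updates) -> "GeneratorPreset":
        params = dict(self.params)
        params.update(updates)
        return GeneratorPreset(self.name, params, self.seed)


@dataclass
class SegregationCounts:
    """Telophase tally: cell counts per plasmid number and the observed
    percentage of each category retaining *all* plasmids in the mother.

    ``a``/``b``/``c`` are ``None`` (undefined, not zero) when the
    corresponding count is zero.
    """

    x: int
    y: int
    z: int
    a: float | None
    b: float | None
    c: float | None

    def __post_init__(self):
        for n in (self.x, self.y, self.z):
            if n < 0:
                raise ValueError("cell counts must be non-negative")
        for count, pct, label in ((self.x, self.a, "a"), (self.y, self.b, "b"),
                                  (self.z, self.c, "c")):
            if pct is not None and not 0.0 <= pct <= 100.0:
                raise ValueError(f"{label}={pct} outside [0, 100]")


@dataclass
class NucleusImage:
    """Single-plane synthetic (or annotated) nucleus image.

    ``pixels`` holds the NPC-reporter (green) channel; ``red`` optionally
    holds the plasmid channel.  ``truth`` records every generating value for
    synthetic images (center, rim radius, cap span/ratio, plasmid angle,
    background, photon budget).
    """

    pixels: np.ndarray
    pixel_size: float
    truth: dict = field(default_factory=dict)
    red: np.ndarray | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixels.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class FluorTrace:
    """Time-stamped ROI fluorescence series with its bleach schedule."""

    t: np.ndarray
    I: np.ndarray
    roi: str = "whole-nucleus"
    bleach_times: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.t.shape != self.I.shape:
            raise ValueError("t and I must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time base must be strictly increasing")
        if self.bleach_times is not None:
            self.bleach_times = np.asarray(self.bleach_times, dtype=float)
            lo, hi = self.t[0], self.t[-1]
            if np.any((self.bleach_times < lo) | (self.bleach_times > hi)):
                raise ValueError("bleach_times outside the acquisition window")


@dataclass
class Track:
    """3-D particle track sampled on a uniform time grid."""

    t: np.ndarray
    xyz: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (self.t.size, 3):
            raise ValueError("xyz must be (n, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")
        dt = np.diff(self.t)
        if dt.size and not np.allclose(dt, dt[0]):
            raise ValueError("time step must be uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class RimProfile:
    """Unrolled nuclear-rim intensity profile.

    Green (NPC reporter) is normalised to its per-cell mean, red (plasmid
    reporter) to its per-cell maximum; ``peak_index`` marks the plasmid
    position on the arc.
    """

    s: np.ndarray
    green: np.ndarray
    red: np.ndarray
    peak_index: int = -1
    truth: dict | None = None

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if not (self.s.shape == self.green.shape == self.red.shape):
            raise ValueError("s, green, red must have equal length")
        gmean = self.green.mean()
        if gmean <= 0:
            raise ValueError("green channel must have positive mean")
        self.green = self.green / gmean
        rmax = self.red.max()
        if rmax > 0:
            self.red = self.red / rmax
        if self.peak_index < 0:
            self.peak_index = int(np.argmax(self.red))

    @property
    def ds(self) -> float:
        return float(self.s[1] - self.s[0])


@dataclass
class DivisionRecord:
    """Mother/bud integrated fluorescence pair at the end of nuclear division."""

    mother_total: float
    bud_total: float
    mother_area: float = math.nan
    bud_area: float = math.nan
    age: int = 0
    label: str = ""

    def __post_init__(self):
        if self.mother_total < 0 or self.bud_total < 0:
            raise ValueError("integrated fluorescence totals must be non-negative")


@dataclass
class PfResult:
    """Propagation-frequency estimate (percent of plasmids passed to the bud)."""

    pf: float
    variant: str
    n_effective: int

    @property
    def per_plasmid_retention(self) -> float:
        return 1.0 - self.pf / 100.0

    def __post_init__(self):
        if not 0.0 <= self.pf <= 100.0:
            raise ValueError(f"pf={self.pf} outside [0, 100]")


@dataclass
class ChipEnrichment:
    """ChIP fold enrichment per locus: (IP/Input) over the untagged control."""

    fold: Mapping[str, float]

    def __post_init__(self):
        for locus, f in dict(self.fold).items():
            if f < 0:
                raise ValueError(f"fold enrichment for {locus} must be >= 0")


@dataclass
class CapQuant:
    """Normalised rim intensities: circle-adjacent (Ic), residual rim (Ir),
    circle-opposite (Io)."""

    Ic: float
    Ir: float
    Io: float | None = None

    def __post_init__(self):
        if self.Ic < 0 or self.Ir < 0 or (self.Io is not None and self.Io < 0):
            raise ValueError("normalised intensities must be non-negative")


@dataclass
class BarrierIndex:
    """Ratio of bud over mother times to lose ``q_lost`` of the initial
    signal during FLIP; > 1 indicates a bud-neck diffusion barrier."""

    value: float
    q_lost: float = 0.40

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("barrier index must be positive")


@dataclass
class AgeingCohort:
    """Output of the stochastic mother-cell simulator."""

    lifespans: np.ndarray
    divisions: pd.DataFrame   # mother, age, circles, npc_mother, npc_bud
    g1: pd.DataFrame          # mother, age, circles, npc_total, radius_proxy
    label: str = ""
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.lifespans = np.asarray(self.lifespans, dtype=int)
        if self.lifespans.size and self.lifespans.min() < 1:
            raise ValueError("lifespans must be >= 1 generation")


@dataclass
class SurvivalSummary:
    """Survival curve and its lower median."""

    median: int
    curve: pd.DataFrame       # age, fraction_alive
    label: str = ""
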