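"""FLIP/FRAP kinetics: acquisition-loss correction, exponential fits,
time-to-fraction statistics and the barrier index.

Decay (FLIP) traces are modelled as ``I(t) = plateau + (100 - plateau) *
exp(-k t)`` on a percent scale where the last pre-bleach point is 100%;
recovery (FRAP) traces as ``I(t) = plateau * (1 - exp(-k t))`` with the
first post-bleach point at 0%.  The time-to-fraction statistics t70, t50,
t40 (decay) and t15 (recovery) are solved from the fitted curve, and the
barrier index is the ratio of the bud over the mother time to lose a set
fraction (default 40%) of the initial signal.

The fits follow the statsmodels idiom: ``ExponentialDecayModel(trace).fit()``
returns a :class:`KineticsFit` carrying parameters, residuals, ``t_q`` and a
``summary()`` table.  The spec-facing functions (``fit_exponential_decay``,
``fit_recovery``, ``time_to_fraction``, ``barrier_index``) are thin wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .datatypes import BarrierIndex, FluorTrace


# ---------------------------------------------------------------------------
# acquisition-loss correction
# ---------------------------------------------------------------------------

def correct_acquisition_loss(trace: FluorTrace, neighbor_traces: list[FluorTrace],
                             kind: str = "decay") -> FluorTrace:
    """Subtract the average fluorescence loss of unbleached neighbor cells,
    then renormalise: decay traces to 100% at the last pre-bleach time
    point, recovery traces to 0% at the first post-bleach point.

    Neighbors must share the target's time base.
    """
    if len(neighbor_traces) < 1:
        raise ValueError("need at least one neighbor trace")
    for nb in neighbor_traces:
        if nb.t.shape != trace.t.shape or not np.allclose(nb.t, trace.t):
            raise ValueError("neighbor trace has a mismatched time base")
    losses = np.stack([nb.I[0] - nb.I for nb in neighbor_traces])
    corrected = trace.I + losses.mean(axis=0)

    bleach = trace.bleach_times
    if kind == "decay":
        if bleach is not None and bleach.size and bleach[0] > trace.t[0]:
            i0 = int(np.searchsorted(trace.t, bleach[0]) - 1)
        else:
            i0 = 0
        ref = corrected[max(i0, 0)]
        if ref <= 0:
            raise ValueError("non-positive reference intensity")
        corrected = 100.0 * corrected / ref
    elif kind == "recovery":
        if bleach is not None and bleach.size:
            i0 = int(np.searchsorted(trace.t, bleach[-1]))
        else:
            i0 = 0
        corrected = corrected - corrected[min(i0, corrected.size - 1)]
    else:
        raise ValueError("kind must be 'decay' or 'recovery'")
    return FluorTrace(t=trace.t.copy(), I=np.clip(corrected, 0.0, None),
                      roi=trace.roi, bleach_times=bleach, normalized=True)


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

@dataclass
class KineticsFit:
    """Converged exponential fit and its derived time statistics."""

    model: str                    # one_phase_decay | one_phase_association
    k: float                      # 1/s
    plateau: float                # % of initial (decay) or of pre-bleach (recovery)
    residual_norm: float
    converged: bool
    n_points: int
    t_q: dict = field(default_factory=dict)

    @property
    def amplitude(self) -> float:
        return 100.0 - self.plateau if self.model == "one_phase_decay" \
            else self.plateau

    def time_to_fraction(self, q: float) -> float:
        """Time at which the fitted curve reaches the level ``100*q``.

        Decay: time until only the fraction ``q`` of the initial signal
        remains.  Recovery: time to recover ``100*q`` percentage points.
        Returns ``inf`` when the level is unreachable (below the plateau of
        a decay, above the plateau of a recovery).
        """
        if not 0.0 <= q <= 1.0:
            raise ValueError("q must lie in [0, 1]")
        level = 100.0 * q
        if self.model == "one_phase_decay":
            if q == 1.0:
                return 0.0
            if level <= self.plateau + 1e-12:
                return math.inf
            return -math.log((level - self.plateau) /
                             (100.0 - self.plateau)) / self.k
        if q == 0.0:
            return 0.0
        if level >= self.plateau - 1e-12:
            return math.inf
        return -math.log(1.0 - level / self.plateau) / self.k

    def summary(self) -> str:
        lines = [f"Kinetics fit: {self.model}",
                 "-" * 36,
                 f"{'k (1/s)':>14s}: {self.k:12.6g}",
                 f"{'plateau (%)':>14s}: {self.plateau:12.6g}",
                 f"{'residual norm':>14s}: {self.residual_norm:12.6g}",
                 f"{'n points':>14s}: {self.n_points:12d}",
                 f"{'converged':>14s}: {str(self.converged):>12s}"]
        for q, tq in sorted(self.t_q.items(), reverse=True):
            label = f"t{int(round(q * 100))} (s)"
            val = "unreachable" if math.isinf(tq) else f"{tq:.6g}"
            lines.append(f"{label:>14s}: {val:>12s}")
        return "\n".join(lines)


class _ExponentialModelBase:
    min_points = 5

    def __init__(self, trace: FluorTrace):
        if trace.t.size < self.min_points:
            raise ValueError(f"need at least {self.min_points} points")
        self.trace = trace


class ExponentialDecayModel(_ExponentialModelBase):
    """One-phase decay ``I = plateau + (100 - plateau) exp(-k t)`` fitted by
    nonlinear least squares.

    Initial values: plateau from the final three points; k from a
    log-linear regression of the first half of the trace.  Non-convergence
    is flagged on the result, never silent.
    """

    model_name = "one_phase_decay"
    default_fractions = (0.7, 0.5, 0.4)

    @staticmethod
    def _curve(t, k, plateau):
        return plateau + (100.0 - plateau) * np.exp(-k * t)

    def _initial(self):
        t, I = self.trace.t, self.trace.I
        plateau0 = float(np.clip(I[-3:].mean(), 0.0, 99.0))
        half = slice(0, max(t.size // 2, 3))
        y = np.clip(I[half] - plateau0, 1e-6, None)
        slope = np.polyfit(t[half], np.log(y), 1)[0]
        k0 = max(-slope, 1e-6)
        return k0, plateau0

    def fit(self, q_fractions=None) -> KineticsFit:
        t, I = self.trace.t, self.trace.I
        q_fractions = q_fractions or self.default_fractions
        k0, plateau0 = self._initial()
        converged = True
        try:
            popt, _ = optimize.curve_fit(
                self._curve, t, I, p0=(k0, plateau0),
                bounds=([1e-12, 0.0], [np.inf, 100.0]),
                xtol=1e-10, ftol=1e-10, maxfev=10000)
            k, plateau = float(popt[0]), float(popt[1])
        except RuntimeError:
            converged = False
            k, plateau = k0, plateau0
        # a flat trace makes k unidentifiable: flag, do not report a rate
        if np.ptp(I) < 1e-9:
            converged = False
            k, plateau = math.nan, float(I.mean())
            resid = 0.0
            fit = KineticsFit(self.model_name, k, plateau, resid, converged,
                              t.size)
            fit.t_q = {q: math.inf for q in q_fractions}
            return fit
        resid = float(np.linalg.norm(I - self._curve(t, k, plateau)))
        fit = KineticsFit(self.model_name, k, plateau, resid, converged, t.size)
        fit.t_q = {q: fit.time_to_fraction(q) for q in q_fractions}
        return fit


class RecoveryModel(_ExponentialModelBase):
    """One-phase association ``I = plateau (1 - exp(-k t))`` for FRAP."""

    model_name = "one_phase_association"
    default_fractions = (0.15,)

    @staticmethod
    def _curve(t, k, plateau):
        return plateau * (1.0 - np.exp(-k * t))

    def fit(self, q_fractions=None) -> KineticsFit:
        t, I = self.trace.t, self.trace.I
        q_fractions = q_fractions or self.default_fractions
        plateau0 = float(np.clip(I[-3:].mean(), 1e-3, 100.0))
        nz = I > 0.05 * plateau0
        k0 = 1.0 / max(float(t[nz][0]) if nz.any() else float(t[-1]), 1e-6)
        converged = True
        try:
            popt, _ = optimize.curve_fit(
                self._curve, t, I, p0=(k0, plateau0),
                bounds=([1e-12, 1e-9], [np.inf, 100.0]),
                xtol=1e-10, ftol=1e-10, maxfev=10000)
            k, plateau = float(popt[0]), float(popt[1])
        except RuntimeError:
            converged = False
            k, plateau = k0, plateau0
        resid = float(np.linalg.norm(I - self._curve(t, k, plateau)))
        fit = KineticsFit(self.model_name, k, plateau, resid, converged, t.size)
        fit.t_q = {q: fit.time_to_fraction(q) for q in q_fractions}
        return fit


def fit_exponential_decay(trace: FluorTrace, q_fractions=None) -> KineticsFit:
    return ExponentialDecayModel(trace).fit(q_fractions)


def fit_recovery(trace: FluorTrace, q_fractions=None) -> KineticsFit:
    return RecoveryModel(trace).fit(q_fractions)


def time_to_fraction(fit: KineticsFit, q_remaining: float) -> float:
    return fit.time_to_fraction(q_remaining)


# ---------------------------------------------------------------------------
# barrier index
# ---------------------------------------------------------------------------

def raw_crossing_time(trace: FluorTrace, level: float) -> float:
    """First time the raw trace crosses ``level`` (linear interpolation);
    for noiseless sanity checks, not the default statistic."""
    I, t = trace.I, trace.t
    below = np.nonzero(I <= level)[0]
    if below.size == 0:
        return math.inf
    i = int(below[0])
    if i == 0:
        return float(t[0])
    f = (I[i - 1] - level) / (I[i - 1] - I[i])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def barrier_index(mother: FluorTrace, bud: FluorTrace,
                  q_lost: float = 0.40) -> BarrierIndex:
    """Ratio of the times needed to lose ``q_lost`` of the initial signal in
    the bud over the mother compartment (bleach applied on the mother side).

    Both times come from one-phase decay fits; a stronger bud-neck barrier
    slows the bud's loss and gives a larger index.
    """
    if not 0.0 < q_lost < 1.0:
        raise ValueError("q_lost must lie in (0, 1)")
    q_remaining = 1.0 - q_lost
    t_m = ExponentialDecayModel(mother).fit((q_remaining,)).t_q[q_remaining]
    t_b = ExponentialDecayModel(bud).fit((q_remaining,)).t_q[q_remaining]
    if math.isinf(t_m) or math.isinf(t_b):
        raise ValueError("loss level unreachable in one of the compartments")
    return BarrierIndex(value=t_b / t_m, q_lost=q_lost)
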