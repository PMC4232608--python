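"""Stochastic mother-cell model of ERC accumulation, NPC co-retention and
replicative lifespan.

Model.  A mother cell starts with no circles.  At each division the circle
count updates as

    C_{g+1} = Binomial(2 * C_g, rho) + Bernoulli(f_form)

— every circle replicates once, each copy stays in the mother independently
with retention fidelity ``rho``, and a new circle forms with probability
``f_form`` per division — so E[C_{g+1}] = 2 rho E[C_g] + f_form.  The cell
dies (senescence proxy) when the circle count reaches ``T_death`` at the
start of a division.  Daughters are not followed: the cohort is
mother-centric, matching microfluidic lifespan assays.

NPCs couple to circles through a saturating-linear mother share: with
``N`` pores and ``min(kappa * C, N)`` of them circle-bound, the fraction
segregated to the mother at division is

    s = s0 + (s_bound - s0) * min(kappa * C, N) / N

with ``s0`` the baseline share of unbound pores and ``s_bound`` the
retention fidelity of bound pores.  After division the mother restores her
pool by constant production ``beta = (1 - s0) * npc_pool``, so a circle-free
nucleus sits at the steady state ``npc_pool``.

``ErcAgeingModel(preset).simulate(n)`` returns an :class:`AgeingCohort`
with per-division records and G1 snapshots; survival statistics, log-rank
comparisons, sensitivity scans and calibration operate on top of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank

from .datatypes import AgeingCohort, GeneratorPreset, SurvivalSummary


class ErcAgeingModel:
    """Mother-cell simulator configured from a preset or keyword overrides."""

    def __init__(self, preset: GeneratorPreset | None = None, **overrides):
        params = dict(preset.params) if preset is not None else {}
        params.update(overrides)
        self.rho = float(params.get("rho_retain", 0.961))
        self.f_form = float(params.get("f_form", 0.05))
        self.T_death = float(params.get("T_death", 1000.0))
        self.s0 = float(params.get("s0", 0.63))
        self.s_bound = float(params.get("s_bound", 0.99))
        self.kappa = float(params.get("kappa", 0.65))
        self.npc_pool = float(params.get("npc_pool", 100.0))
        self.max_age = int(params.get("max_age", 300))
        self.init_circles = int(params.get("init_circles", 0))
        self.death_mode = str(params.get("death_mode", "threshold"))
        if self.death_mode not in ("threshold", "hazard"):
            raise ValueError("death_mode must be 'threshold' or 'hazard'")
        self.label = preset.name if preset is not None else params.get("label", "")
        self.default_seed = preset.seed if preset is not None else 0
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.T_death < 2:
            raise ValueError("T_death must be >= 2")
        if not self.s0 <= self.s_bound <= 1.0:
            raise ValueError("need s0 <= s_bound <= 1")

    def _npc_share(self, C: np.ndarray, N: np.ndarray) -> np.ndarray:
        bound = np.minimum(self.kappa * C, N)
        return self.s0 + (self.s_bound - self.s0) * bound / N

    def simulate(self, n_mothers: int, seed: int | None = None,
                 record: bool = True) -> AgeingCohort:
        """Simulate a cohort; deterministic given (parameters, seed)."""
        rng = np.random.default_rng(self.default_seed if seed is None else seed)
        C = np.full(n_mothers, self.init_circles, dtype=np.int64)
        N = np.full(n_mothers, self.npc_pool, dtype=float)
        alive = np.ones(n_mothers, dtype=bool)
        lifespan = np.full(n_mothers, self.max_age, dtype=np.int64)
        beta = (1.0 - self.s0) * self.npc_pool
        div_rows, g1_rows = [], []

        for age in range(1, self.max_age + 1):
            if self.death_mode == "threshold":
                dying = alive & (C >= self.T_death)
            else:  # hazard alternative: death prob 1 - exp(-C / T_death)
                hazard = 1.0 - np.exp(-C / self.T_death)
                dying = alive & (rng.random(n_mothers) < hazard)
            lifespan[dying] = age - 1
            alive &= ~dying
            if not alive.any():
                break
            idx = np.nonzero(alive)[0]
            s = self._npc_share(C[idx], N[idx])
            npc_mother = s * N[idx]
            npc_bud = (1.0 - s) * N[idx]
            C_next = rng.binomial(2 * C[idx], self.rho) + \
                (rng.random(idx.size) < self.f_form).astype(np.int64)
            if record:
                div_rows.append(pd.DataFrame({
                    "mother": idx, "age": age, "circles": C[idx],
                    "npc_mother": npc_mother, "npc_bud": npc_bud}))
            N_next = npc_mother + beta
            if record:
                g1_rows.append(pd.DataFrame({
                    "mother": idx, "age": age, "circles": C_next,
                    "npc_total": N_next,
                    "radius_proxy": (N_next / self.npc_pool) ** (1.0 / 3.0)}))
            C[idx] = C_next
            N[idx] = N_next

        empty_div = pd.DataFrame(columns=["mother", "age", "circles",
                                          "npc_mother", "npc_bud"])
        empty_g1 = pd.DataFrame(columns=["mother", "age", "circles",
                                         "npc_total", "radius_proxy"])
        divisions = pd.concat(div_rows, ignore_index=True) if div_rows else empty_div
        g1 = pd.concat(g1_rows, ignore_index=True) if g1_rows else empty_g1
        return AgeingCohort(lifespans=lifespan, divisions=divisions, g1=g1,
                            label=self.label,
                            params=dict(rho=self.rho, f_form=self.f_form,
                                        T_death=self.T_death, s0=self.s0,
                                        s_bound=self.s_bound, kappa=self.kappa,
                                        npc_pool=self.npc_pool))


def simulate_cohort(preset: GeneratorPreset, n_mothers: int,
                    seed: int | None = None) -> AgeingCohort:
    return ErcAgeingModel(preset).simulate(n_mothers, seed=seed)


# ---------------------------------------------------------------------------
# survival statistics
# ---------------------------------------------------------------------------

def _lower_median(values: np.ndarray) -> int:
    v = np.sort(np.asarray(values))
    return int(v[math.ceil(v.size / 2) - 1])


def survival_summary(cohort: AgeingCohort | np.ndarray,
                     label: str | None = None) -> SurvivalSummary:
    """Survival curve (fraction alive after each division count) and its
    lower median: the first age at which the curve drops to 0.5 or below."""
    lifespans = cohort.lifespans if isinstance(cohort, AgeingCohort) \
        else np.asarray(cohort, dtype=int)
    if lifespans.size == 0:
        raise ValueError("empty cohort")
    ages = np.arange(0, lifespans.max() + 1)
    frac = np.array([(lifespans > a).mean() for a in ages])
    curve = pd.DataFrame({"age": ages, "fraction_alive": frac})
    if label is None:
        label = cohort.label if isinstance(cohort, AgeingCohort) else ""
    return SurvivalSummary(median=_lower_median(lifespans), curve=curve,
                           label=label)


@dataclass
class LogrankResult:
    statistic: float
    p_value: float

    def summary(self) -> str:
        return f"log-rank: chi2={self.statistic:.4g}, p={self.p_value:.4g}"


def logrank_compare(a, b) -> LogrankResult:
    """Log-rank (Mantel-Cox) comparison of two lifespan samples (no
    censoring in simulated cohorts)."""
    la = a.lifespans if isinstance(a, AgeingCohort) else np.asarray(a)
    lb = b.lifespans if isinstance(b, AgeingCohort) else np.asarray(b)
    res = _lifelines_logrank(la, lb, event_observed_A=np.ones_like(la),
                             event_observed_B=np.ones_like(lb))
    return LogrankResult(statistic=float(res.test_statistic),
                         p_value=float(res.p_value))


# ---------------------------------------------------------------------------
# sensitivity scan
# ---------------------------------------------------------------------------

def retention_sensitivity_scan(preset: GeneratorPreset, rho_grid,
                               n_mothers: int = 200, n_rep: int = 3,
                               seed: int | None = None,
                               age_bins: int = 10):
    """One cohort per retention-fidelity grid point (replicated), sharing a
    spawned seed stream.  Returns ``(table, profiles)`` where the table has
    the mean median lifespan per rho (with a monotonicity flag) and
    ``profiles[rho]`` holds the ERC-count and NPC-mother-share age profiles.
    """
    rho_grid = [float(r) for r in rho_grid]
    ss = np.random.SeedSequence(preset.seed if seed is None else seed)
    children = ss.spawn(len(rho_grid) * n_rep)
    rows, profiles = [], {}
    for i, rho in enumerate(rho_grid):
        medians = []
        prof_frames = []
        for rep in range(n_rep):
            child = children[i * n_rep + rep]
            cseed = int(child.generate_state(1)[0] % (2 ** 31))
            cohort = ErcAgeingModel(preset, rho_retain=rho).simulate(
                n_mothers, seed=cseed, record=(rep == 0))
            medians.append(survival_summary(cohort).median)
            if rep == 0 and len(cohort.divisions):
                d = cohort.divisions
                share = d["npc_mother"] / (d["npc_mother"] + d["npc_bud"])
                prof_frames.append(pd.DataFrame({
                    "age": d["age"], "circles": d["circles"], "npc_share": share}))
        rows.append((rho, float(np.mean(medians))))
        if prof_frames:
            prof = prof_frames[0]
            prof["age_bin"] = pd.cut(prof["age"], bins=age_bins)
            profiles[rho] = prof.groupby("age_bin", observed=True)[
                ["circles", "npc_share"]].mean().reset_index()
    table = pd.DataFrame(rows, columns=["rho", "median_lifespan"])
    diffs = np.diff(table["median_lifespan"].to_numpy())
    table.attrs["monotone_nonincreasing"] = bool(np.all(diffs <= 0))
    return table, profiles


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    params: dict
    achieved_median: float
    target_median: float
    ok: bool
    history: pd.DataFrame

    def summary(self) -> str:
        status = "converged" if self.ok else "FAILED (target unreachable)"
        return (f"Calibration {status}: target median {self.target_median}, "
                f"achieved {self.achieved_median:.1f} with "
                f"f_form={self.params['f_form']:.3g}, "
                f"T_death={self.params['T_death']:.6g}")


def calibrate_to_wt(target_median: float, rho: float | None = None,
                    pf: float | None = None,
                    preset: GeneratorPreset | None = None,
                    n_mothers: int = 200, n_rep: int = 2, seed: int = 1,
                    f_form_grid=None, tol: float = 2.0) -> CalibrationResult:
    """Fit (f_form, T_death) so a simulated cohort reproduces the target
    median lifespan, with rho fixed (directly or as 1 - pf/100).

    Deterministic grid search over f_form and log2(T_death), followed by a
    bisection refinement of T_death at the best formation rate.  ``ok`` is
    False (with the best attempt reported) when the target is unreachable
    within the parameter bounds.
    """
    if rho is None:
        if pf is None:
            raise ValueError("provide rho or pf")
        rho = 1.0 - pf / 100.0
    base = dict(preset.params) if preset is not None else {}
    base["rho_retain"] = rho
    if f_form_grid is None:
        f_form_grid = (0.02, 0.04, 0.06, 0.1, 0.2)
    ss = np.random.SeedSequence(seed)

    def median_for(f_form: float, T: float, sub) -> float:
        meds = []
        for child in sub.spawn(n_rep):
            cseed = int(child.generate_state(1)[0] % (2 ** 31))
            model = ErcAgeingModel(None, **{**base, "f_form": f_form,
                                            "T_death": T})
            cohort = model.simulate(n_mothers, seed=cseed, record=False)
            meds.append(survival_summary(cohort).median)
        return float(np.mean(meds))

    history = []
    best = None
    log2T_grid = np.arange(3.0, 17.0)
    for f_form in f_form_grid:
        for log2T in log2T_grid:
            med = median_for(f_form, 2.0 ** log2T, ss.spawn(1)[0])
            history.append((f_form, 2.0 ** log2T, med))
            err = abs(med - target_median)
            if best is None or err < best[0]:
                best = (err, f_form, log2T, med)

    _, f_best, log2T_best, med_best = best
    lo, hi = log2T_best - 1.0, log2T_best + 1.0
    for _ in range(12):
        mid = 0.5 * (lo + hi)
        med = median_for(f_best, 2.0 ** mid, ss.spawn(1)[0])
        history.append((f_best, 2.0 ** mid, med))
        if abs(med - target_median) < abs(med_best - target_median):
            med_best, log2T_best = med, mid
        if med < target_median:
            lo = mid            # median lifespan increases with T_death
        else:
            hi = mid

    params = {**base, "f_form": f_best, "T_death": 2.0 ** log2T_best}
    ok = abs(med_best - target_median) <= tol
    return CalibrationResult(params=params, achieved_median=med_best,
                             target_median=float(target_median), ok=ok,
                             history=pd.DataFrame(
                                 history, columns=["f_form", "T_death", "median"]))
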