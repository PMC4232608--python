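"""Study-condition presets for the synthetic-data generators.

Each preset bundles the parameter values that define a genotype or imaging
condition: per-plasmid propagation probabilities from the telophase
segregation assay, cap intensity ratios and photon budgets from the
NPC-reporter imaging, FLIP/FRAP rate constants, diffusion step sizes from
plasmid tracking, and the retention/formation/death parameters of the
replicative-ageing simulator.  Values are the package's calibration
constants; ``manifest()`` exports them for provenance.
"""

from __future__ import annotations

import math

from .datatypes import GeneratorPreset

#: Mean of a chi distribution with 3 degrees of freedom (unit scale):
#: the expected 3-D step length for isotropic Gaussian steps of per-axis SD 1.
CHI3_MEAN = math.sqrt(2.0) * math.gamma(2.0) / math.gamma(1.5)

#: Observed mix of telophase cells carrying 1 / 2 / 4 plasmid foci.
DEFAULT_COUNT_MIX = (0.61, 0.33, 0.06)

#: FLIP acquisition grid: repeated bleaching at 9 s intervals, 30 time points.
FLIP_DT, FLIP_N = 9.0, 30

#: Plasmid tracking grid: one 3-D position every 3 s for 3 min (61 points).
TRACK_DT, TRACK_N = 3.0, 61


def _step_sigma(mean_speed_um_s: float, dt: float = TRACK_DT) -> float:
    """Per-axis step SD giving the requested mean 3-D speed per interval."""
    return mean_speed_um_s * dt / CHI3_MEAN


_IMAGE_DEFAULTS = dict(
    shape=(64, 64),
    pixel_size=0.07,        # um per pixel; frame half-extent ~2.2 um keeps rim tails inside
    rim_radius=1.0,         # um
    rim_blur_sd=0.25,       # um, stands in for the optical PSF
    cap_span=math.pi / 2,   # rad
    background=2.0,         # counts per pixel
    gain=1.0,               # Poisson shot noise scale; 0 disables
    read_noise_sd=1.0,      # additive Gaussian SD in counts; 0 disables
)

_RIM_PROFILE_DEFAULTS = dict(
    rim_radius=1.0,         # um
    n_samples=256,          # arc step 2*pi*R/256 ~ 24.5 nm (< 65 nm)
    bump_sd=0.060,          # um, width of the NPC enrichment bump
    window_um=0.130,        # um, analysis half-window around the plasmid peak
    noise_sd=0.03,          # correlated green noise, fraction of baseline
    noise_corr_um=0.05,     # smoothing length of the correlated noise
    red_peak_sd=0.040,      # um
    red_noise_sd=0.02,
)

_AGEING_DEFAULTS = dict(
    rho_retain=0.961,       # per-circle-copy mother-retention probability (1 - pf/100)
    f_form=0.1,             # circle-formation probability per division
    T_death=262144.0,       # circle-count death threshold (2**18)
    s0=0.63,                # NPC mother share with no circles bound
    s_bound=0.99,           # retention fidelity of circle-bound pores
    kappa=0.65,             # pores bound per circle
    npc_pool=100.0,         # steady-state pore count of a young nucleus
    max_age=300,
)


def _preset(name: str, seed: int, **params) -> GeneratorPreset:
    return GeneratorPreset(name=name, params=params, seed=seed)


PRESETS: dict[str, GeneratorPreset] = {}


def register(preset: GeneratorPreset) -> GeneratorPreset:
    PRESETS[preset.name] = preset
    return preset


# --- segregation / pedigree / colony presets (per-plasmid propagation) -----
# p_prop is the propagation-frequency point estimate divided by 100.
for _name, _pf in [("wt", 3.9), ("gcn5", 11.1), ("bud6", 11.8), ("sgf73", 11.8),
                   ("spt3", 9.7), ("sus1", 11.3), ("sac3", 11.5), ("yku70", 10.3),
                   ("gcn5-tetr", 1.1)]:
    register(_preset(
        _name, seed=101,
        p_prop=_pf / 100.0,
        count_mix=DEFAULT_COUNT_MIX,
        pedigree_k=24,              # circles per aged mother in the pedigree assay
        p_excise=0.01, p_first_loss=0.5,
        rho_retain=1.0 - _pf / 100.0,
    ))

# --- nucleus-image presets --------------------------------------------------
register(_preset(
    "wt-loaded", seed=202, loaded=True,
    cap_ratio=2.02, photons=54000.0, p_interior=0.15,
    pct_mother_median=0.78, pct_mother_sd=0.06,
    division_total=4000.0, division_total_sd=600.0,
    **_IMAGE_DEFAULTS,
))
register(_preset(
    "bud6-loaded", seed=202, loaded=True,
    cap_ratio=2.29, photons=54000.0, p_interior=0.15,
    pct_mother_median=0.78, pct_mother_sd=0.06,
    division_total=4000.0, division_total_sd=600.0,
    **_IMAGE_DEFAULTS,
))
register(_preset(
    "unloaded", seed=203, loaded=False,
    cap_ratio=1.0, photons=20000.0,
    pct_mother_median=0.63, pct_mother_sd=0.06,
    division_total=1500.0, division_total_sd=250.0,
    **_IMAGE_DEFAULTS,
))

# --- rim-profile (plasmid/NPC co-localisation) presets ----------------------
register(_preset("rim-wt", seed=303, enrichment=0.332, **_RIM_PROFILE_DEFAULTS))
register(_preset("rim-gcn5", seed=303, enrichment=0.046, **_RIM_PROFILE_DEFAULTS))
register(_preset("rim-sus1", seed=303, enrichment=-0.020, **_RIM_PROFILE_DEFAULTS))
register(_preset("rim-null", seed=303, enrichment=0.0, **_RIM_PROFILE_DEFAULTS))

# --- FLIP / FRAP presets ----------------------------------------------------
# Decay rates are the analytic inversion k = ln(10/7) / t70 of the reported
# circle-adjacent (82 s) and circle-opposite (25 s) loss times.
register(_preset(
    "flip-wt-circle", seed=404,
    k_a=math.log(10.0 / 7.0) / 82.0, roi_a="circle-adjacent",
    k_b=math.log(10.0 / 7.0) / 25.0, roi_b="opposite",
    immobile_frac=0.0, dt=FLIP_DT, n_points=FLIP_N, noise_sd=1.0,
))
# Mother/bud pairs for the barrier index: a strong barrier slows loss from
# the (unbleached) bud; in bud6-like cells both compartments decay alike.
register(_preset(
    "flip-barrier-wt", seed=405,
    k_a=0.030, roi_a="mother", k_b=0.006, roi_b="bud",
    immobile_frac=0.0, dt=FLIP_DT, n_points=FLIP_N, noise_sd=1.0,
))
register(_preset(
    "flip-barrier-bud6", seed=405,
    k_a=0.030, roi_a="mother", k_b=0.030, roi_b="bud",
    immobile_frac=0.0, dt=FLIP_DT, n_points=FLIP_N, noise_sd=1.0,
))
register(_preset(
    "frap-stable-pore", seed=406,     # core nucleoporin: slow exchange
    k_recovery=0.005, plateau=60.0, dt=TRACK_DT, n_points=TRACK_N, noise_sd=1.0,
))
register(_preset(
    "frap-shuttling-pore", seed=406,  # basket protein: fast exchange
    k_recovery=0.08, plateau=90.0, dt=TRACK_DT, n_points=TRACK_N, noise_sd=1.0,
))

# --- plasmid-tracking presets ----------------------------------------------
register(_preset("track-wt", seed=505, sigma_step=_step_sigma(0.05),
                 dt=TRACK_DT, n_points=TRACK_N))
register(_preset("track-gcn5", seed=505, sigma_step=_step_sigma(0.09),
                 dt=TRACK_DT, n_points=TRACK_N))

# --- ageing-simulator presets ----------------------------------------------
register(_preset("ageing-wt", seed=606, **_AGEING_DEFAULTS))
register(_preset("ageing-bud6", seed=606, **{**_AGEING_DEFAULTS, "rho_retain": 0.88}))
register(_preset("ageing-fob1", seed=606, **{**_AGEING_DEFAULTS, "f_form": 0.025}))


def get_preset(name: str) -> GeneratorPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def manifest() -> dict:
    """All presets as plain nested dicts (for the fixtures manifest)."""
    return {name: {"seed": p.seed, "params": {k: v for k, v in p.params.items()}}
            for name, p in sorted(PRESETS.items())}
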