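"""Retention statistics: the propagation-frequency (pf) estimator, pedigree
retention frequency, half-sector formation rate, ChIP fold enrichment and
group comparisons.

The pf estimator summarises a telophase tally of cells carrying 1, 2 or 4
plasmids.  Writing ``a``, ``b``, ``c`` for the percentage of each category
retaining *all* plasmids, the per-plasmid retention of an m-plasmid cell is
the m-th root of its all-retained fraction, and pf is 100 minus the
plasmid-weighted average of those retentions:

    pf = 100 - (x*R1 + 2y*R2 + 4z*R4) / (x + 2y + 4z)

The default ``consistent`` variant rescales each root back to percent
(R2 = 100*sqrt(b/100), R4 = 100*(c/100)**0.25), which makes pf an unbiased
estimate of 100p when each plasmid propagates independently with
probability p.  The historical formula that applies the roots to the raw
0-100 percentages is kept as variant ``as_printed``; the two agree only
when b = c = 100 or when b, c are read on a 0-1 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ChipEnrichment, PfResult, SegregationCounts

VARIANTS = ("consistent", "as_printed")


def compute_pf(counts: SegregationCounts, variant: str = "consistent") -> PfResult:
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    x, y, z = counts.x, counts.y, counts.z
    n_eff = x + 2 * y + 4 * z
    if n_eff <= 0:
        raise ValueError("x + 2y + 4z must be positive")
    for count, pct, label in ((x, counts.a, "a"), (y, counts.b, "b"),
                              (z, counts.c, "c")):
        if count > 0 and pct is None:
            raise ValueError(f"category with nonzero count has undefined {label}")
        if pct is not None and pct < 0:
            raise ValueError(f"{label} must be non-negative")

    a = counts.a if counts.a is not None else 0.0
    b = counts.b if counts.b is not None else 0.0
    c = counts.c if counts.c is not None else 0.0
    if variant == "consistent":
        r1 = a
        r2 = 100.0 * (b / 100.0) ** 0.5
        r4 = 100.0 * (c / 100.0) ** 0.25
    else:  # literal reading of the printed formula
        r1 = a
        r2 = b ** 0.5
        r4 = c ** 0.25
    pf = 100.0 - (x * r1 + 2 * y * r2 + 4 * z * r4) / n_eff
    return PfResult(pf=pf, variant=variant, n_effective=n_eff)


def pedigree_retention_frequency(table: pd.DataFrame) -> float:
    """Percentage of mothers whose daughter lacks the circle marker, i.e.
    all circles stayed in the mother."""
    if len(table) == 0:
        raise ValueError("empty pedigree table")
    lacking = ~table["daughter_has_marker"].astype(bool)
    return 100.0 * float(lacking.mean())


def half_sector_rate(table: pd.DataFrame) -> float:
    """Half-sectored colonies over total colonies (exact division)."""
    total = len(table)
    if total == 0:
        raise ValueError("empty colony table")
    half = int((table["sector_class"] == "half").sum())
    return half / total


def chip_fold_enrichment(ip, input_, ip_ctrl, input_ctrl,
                         loci=None) -> ChipEnrichment:
    """(IP/Input) of the tagged strain over the same ratio in the untagged
    control; scalars give one locus, arrays one fold per locus."""
    ip = np.atleast_1d(np.asarray(ip, dtype=float))
    input_ = np.atleast_1d(np.asarray(input_, dtype=float))
    ip_ctrl = np.atleast_1d(np.asarray(ip_ctrl, dtype=float))
    input_ctrl = np.atleast_1d(np.asarray(input_ctrl, dtype=float))
    if np.any(ip <= 0) or np.any(input_ <= 0) or np.any(ip_ctrl <= 0) \
            or np.any(input_ctrl <= 0):
        raise ValueError("all signals must be strictly positive")
    fold = (ip / input_) / (ip_ctrl / input_ctrl)
    if loci is None:
        loci = [f"locus{i}" for i in range(fold.size)]
    return ChipEnrichment(fold=dict(zip(loci, map(float, fold))))


@dataclass
class GroupComparison:
    """Result of an omnibus test plus (optionally) per-group comparisons
    against a reference."""

    design: str
    statistic: float | None
    df: tuple | None
    p_value: float | None
    comparisons: pd.DataFrame | None
    degenerate: bool = False

    def summary(self) -> str:
        if self.degenerate:
            return f"{self.design}: degenerate input (zero variance); no p-value"
        lines = [f"{self.design}: statistic={self.statistic:.4g}, "
                 f"df={self.df}, p={self.p_value:.4g}"]
        if self.comparisons is not None:
            lines.append(self.comparisons.to_string(index=False))
        return "\n".join(lines)


def compare_groups(values_by_group: dict, design: str = "anova_dunnett",
                   reference: str | None = None) -> GroupComparison:
    """Compare >= 2 groups: one-way ANOVA followed by Dunnett's test against
    a reference group, or an unpaired two-tailed t-test for two groups.

    Zero variance in every group is flagged as degenerate rather than
    producing a fabricated p-value.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    if all(np.var(v) == 0 for v in groups.values()):
        return GroupComparison(design=design, statistic=None, df=None,
                               p_value=None, comparisons=None, degenerate=True)

    names = list(groups)
    if design == "ttest":
        if len(groups) != 2:
            raise ValueError("t-test design requires exactly two groups")
        va, vb = groups[names[0]], groups[names[1]]
        res = stats.ttest_ind(va, vb)
        return GroupComparison(design="ttest", statistic=float(res.statistic),
                               df=(va.size + vb.size - 2,),
                               p_value=float(res.pvalue), comparisons=None)
    if design != "anova_dunnett":
        raise ValueError("design must be 'anova_dunnett' or 'ttest'")

    if reference is None:
        reference = names[0]
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    f_res = stats.f_oneway(*groups.values())
    others = [n for n in names if n != reference]
    dunnett = stats.dunnett(*[groups[n] for n in others],
                            control=groups[reference])
    comparisons = pd.DataFrame({
        "group": others,
        "statistic": np.atleast_1d(dunnett.statistic),
        "p_adjusted": np.atleast_1d(dunnett.pvalue),
        "reference": reference,
    })
    k = len(groups)
    n_tot = sum(v.size for v in groups.values())
    return GroupComparison(design="anova_dunnett",
                           statistic=float(f_res.statistic),
                           df=(k - 1, n_tot - k),
                           p_value=float(f_res.pvalue),
                           comparisons=comparisons)
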