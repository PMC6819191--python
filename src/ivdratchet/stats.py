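"""Statistical layer on cohort outputs.

Condition endpoint tables (ratcheting strain and compression stiffness at a
chosen cycle, default the 400th), Pearson correlations between endpoints
and loading factors, one-way ANOVA across groups, and a directional-effect
report mirroring the findings of disc ratcheting experiments: ratcheting
strain rises with stress variation and falls with stress rate, stiffness
rises with both, and L6-7 discs ratchet less than L5-6. Two-sided tests
throughout; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cycles import RatchetingCurve

__all__ = [
    "UndefinedCorrelationError",
    "StatResult",
    "EffectDirection",
    "SegmentComparison",
    "EffectDirectionReport",
    "pearson",
    "anova_oneway",
    "endpoint_table",
    "effect_direction_report",
    "plot_ratcheting_curves",
    "plot_endpoint_bars",
]

ENDPOINT_COLUMNS = [
    "stress_variation",
    "stress_rate",
    "segment",
    "replicate",
    "ratcheting_strain",
    "stiffness_N_per_mm",
]


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (zero variance in an input)."""


@dataclass(frozen=True)
class StatResult:
    """A test statistic (Pearson R or ANOVA F) with its two-sided p-value."""

    statistic: float
    p_value: float
    kind: str
    group_labels: tuple = ()
    n_per_group: tuple = ()

    def __post_init__(self) -> None:
        if self.kind == "pearson" and not (-1.0 - 1e-12 <= self.statistic <= 1.0 + 1e-12):
            raise ValueError("Pearson R must lie in [-1, 1]")
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


def pearson(x, y) -> StatResult:
    """Pearson correlation with two-sided p-value (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson needs two equal-length samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    res = sps.pearsonr(x, y)
    return StatResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        kind="pearson",
        n_per_group=(int(x.size),),
    )


def anova_oneway(groups: Sequence, labels: Optional[Sequence[str]] = None) -> StatResult:
    """One-way ANOVA F statistic and p-value across >= 2 groups of n >= 2."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    pooled = np.concatenate(arrays)
    if not np.all(np.isfinite(pooled)):
        raise ValueError("inputs must be finite")
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate groups: all observations identical")
    grand = pooled.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    if ss_between == 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = (float(v) for v in sps.f_oneway(*arrays))
    return StatResult(
        statistic=float(f_stat),
        p_value=float(p),
        kind="anova",
        group_labels=tuple(labels) if labels is not None else tuple(range(len(arrays))),
        n_per_group=tuple(int(a.size) for a in arrays),
    )


def endpoint_table(
    curves: Sequence[RatchetingCurve], endpoint_cycle: int = 400
) -> pd.DataFrame:
    """One row per replicate: condition factors and endpoint metrics.

    The endpoint cycle defaults to 400 but is configurable (some protocols
    run 200 cycles).
    """
    if not curves:
        raise ValueError("no curves supplied")
    rows = []
    for c in curves:
        eps = c.at_cycle(endpoint_cycle)
        stiff = np.nan
        if c.stiffness is not None:
            stiff = c.stiffness_at_cycle(endpoint_cycle)
        if not np.isfinite(eps):
            raise ValueError("non-finite endpoint ratcheting strain")
        rows.append(
            (
                c.stress_variation,
                c.stress_rate,
                c.segment,
                c.replicate,
                eps,
                stiff,
            )
        )
    return pd.DataFrame(rows, columns=ENDPOINT_COLUMNS)


@dataclass(frozen=True)
class EffectDirection:
    """Sign of one factor-response correlation."""

    factor: str
    response: str
    r: float
    p_value: float
    direction: str  # '+' or '-'
    n: int
    held_fixed: str = ""


@dataclass(frozen=True)
class SegmentComparison:
    """Mean-endpoint comparison across spinal segments."""

    means: dict
    lower_segment: Optional[str]
    difference: float
    anova: Optional[StatResult]


@dataclass
class EffectDirectionReport:
    """Signs of the loading-factor effects plus the segment comparison.

    Magnitudes are data-dependent; only directions (and their p-values)
    are meaningful for comparison with published disc experiments.
    """

    endpoint_cycle: int
    effects: list = field(default_factory=list)
    segments: Optional[SegmentComparison] = None

    def effect(self, factor: str, response: str) -> EffectDirection:
        for e in self.effects:
            if e.factor == factor and e.response == response:
                return e
        raise KeyError(f"no effect entry for {factor} -> {response}")

    def to_text(self) -> str:
        lines = [
            f"Directional effect report (endpoint cycle {self.endpoint_cycle})",
            "Note: correlation magnitudes are data-dependent; compare signs only.",
        ]
        for e in self.effects:
            fixed = f" at fixed {e.held_fixed}" if e.held_fixed else ""
            lines.append(
                f"  {e.response} vs {e.factor}{fixed}: R = {e.r:+.3f} "
                f"(P = {e.p_value:.3g}, n = {e.n}) -> {e.direction}"
            )
        if self.segments is not None:
            s = self.segments
            means = ", ".join(f"{k}: {v:.4g}" for k, v in s.means.items())
            p = f", ANOVA P = {s.anova.p_value:.3g}" if s.anova else ""
            lines.append(
                f"  segment means ({means}); lower: {s.lower_segment}{p}"
            )
        return "\n".join(lines)


def _factor_subset(table: pd.DataFrame, factor: str, other: str) -> pd.DataFrame:
    """Rows at the level of `other` that spans the most `factor` levels."""
    best = None
    for level, sub in table.groupby(other, dropna=False):
        if sub[factor].nunique() >= 2 and (best is None or len(sub) > len(best[1])):
            best = (level, sub)
    if best is None:
        return table.iloc[0:0]
    return best[1]


def effect_direction_report(
    table: pd.DataFrame, endpoint_cycle: int = 400
) -> EffectDirectionReport:
    """Correlation signs of endpoints against Δσ and stress rate, plus segments.

    For each factor the analysis is restricted to the level of the other
    factor with the widest coverage, so the correlations are one-factor-at-
    a-time as in the underlying experiments. Raises if neither factor spans
    two levels.
    """
    report = EffectDirectionReport(endpoint_cycle=endpoint_cycle)
    pairs = [
        ("stress_variation", "stress_rate"),
        ("stress_rate", "stress_variation"),
    ]
    for factor, other in pairs:
        sub = _factor_subset(table, factor, other)
        if len(sub) < 3:
            continue
        for response in ("ratcheting_strain", "stiffness_N_per_mm"):
            vals = sub[response]
            if vals.isna().any():
                continue
            res = pearson(sub[factor], vals)
            report.effects.append(
                EffectDirection(
                    factor=factor,
                    response=response,
                    r=res.statistic,
                    p_value=res.p_value,
                    direction="+" if res.statistic >= 0 else "-",
                    n=len(sub),
                    held_fixed=f"{other}={sub[other].iloc[0]:g}",
                )
            )
    if not report.effects:
        raise ValueError("no factor spans at least two levels")

    segs = [s for s in table["segment"].dropna().unique() if s is not None]
    if len(segs) >= 2:
        # compare segments only on loading conditions tested in all of them,
        # so unbalanced cells do not confound the means
        cells = table.groupby(["stress_variation", "stress_rate"])["segment"].nunique()
        shared = cells[cells == len(segs)].index
        matched = table.set_index(["stress_variation", "stress_rate"])
        matched = matched.loc[matched.index.isin(shared)].reset_index()
        if matched.empty:
            matched = table
        groups = [
            matched.loc[matched["segment"] == s, "ratcheting_strain"].to_numpy()
            for s in segs
        ]
        means = {s: float(np.mean(g)) for s, g in zip(segs, groups)}
        anova = None
        if all(len(g) >= 2 for g in groups):
            try:
                anova = anova_oneway(groups, labels=segs)
            except ValueError:
                anova = None
        diffs = sorted(means.items(), key=lambda kv: kv[1])
        lower = diffs[0][0] if diffs[0][1] < diffs[-1][1] else None
        report.segments = SegmentComparison(
            means=means,
            lower_segment=lower,
            difference=float(diffs[-1][1] - diffs[0][1]),
            anova=anova,
        )
    return report


# --------------------------------------------------------------------------
# optional figures
# --------------------------------------------------------------------------


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_ratcheting_curves(curves: Sequence[RatchetingCurve], path) -> None:
    """Ratcheting strain evolution, one line per curve, labelled by condition."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for c in curves:
        label = f"Δσ={c.stress_variation}, rate={c.stress_rate}"
        if c.segment:
            label += f", {c.segment}"
        ax.plot(c.cycle_indices, c.ratcheting_strain, lw=1, label=label)
    ax.set_xlabel("cycle N")
    ax.set_ylabel("ratcheting strain (compression positive)")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_endpoint_bars(table: pd.DataFrame, path, response: str = "stiffness_N_per_mm") -> None:
    """Bar chart of an endpoint metric by loading condition."""
    plt = _pyplot()
    grouped = (
        table.groupby(["stress_variation", "stress_rate"])[response]
        .agg(["mean", "std"])
        .reset_index()
    )
    labels = [
        f"{r.stress_variation:g}/{r.stress_rate:g}" for r in grouped.itertuples()
    ]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(labels, grouped["mean"], yerr=grouped["std"].fillna(0.0), capsize=3)
    ax.set_xlabel("Δσ (MPa) / rate (MPa/s)")
    ax.set_ylabel(response)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
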