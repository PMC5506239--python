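"""Toxicity normalization, MIC determination, growth kinetics, ANOVA.

CFU counts from a concentration x incubation-time toxicity design are
normalized to the untreated control at the same time point; the minimal
inhibitory concentration (MIC) is the lowest tested concentration whose
mean normalized survival drops by more than a threshold (20% by
convention here), optionally additionally requiring Tukey-adjusted
significance against the control. Growth curves (OD600 vs time) yield a
doubling time from the log-linear exponential phase, and the full
toxicity table is analysed as a two-factor fixed-effects design with
interaction plus Tukey HSD pairwise comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "CFUToxicityTable",
    "GrowthCurve",
    "AnovaResult",
    "normalized_cfu",
    "minimal_inhibitory_concentration",
    "doubling_time",
    "two_factor_anova",
]

TOXICITY_COLUMNS = ("concentration", "time_h", "replicate", "cfu_count")


@dataclass(frozen=True)
class CFUToxicityTable:
    """Replicate CFU counts by concentration x incubation time.

    ``data`` columns: ``concentration`` (mg/L or particles per cell;
    0 marks the control), ``time_h``, ``replicate``, ``cfu_count``.
    Every time point must include a concentration-0 control row.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(TOXICITY_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"toxicity table missing columns: {sorted(missing)}")
        if len(self.data) == 0:
            raise ValueError("toxicity table is empty")
        if (self.data["cfu_count"] < 0).any():
            raise ValueError("CFU counts must be >= 0")
        for t, sub in self.data.groupby("time_h"):
            if not (sub["concentration"] == 0).any():
                raise ValueError(f"no concentration-0 control at time {t} h")

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.data["concentration"].unique())

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["time_h"].unique())


@dataclass(frozen=True)
class GrowthCurve:
    """Timed OD600 measurements; times in minutes, strictly increasing."""

    times: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od600", od)
        if t.shape != od.shape or t.ndim != 1:
            raise ValueError("times and od600 must be 1-d arrays of equal length")
        if len(t) < 4:
            raise ValueError("growth curve needs at least 4 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(od > 0):
            raise ValueError("OD600 must be positive")


@dataclass(frozen=True)
class AnovaResult:
    """Two-way ANOVA table plus per-time Tukey pairwise comparisons."""

    anova_table: pd.DataFrame  # rows: factors, interaction, Residual
    tukey_tables: dict = field(default_factory=dict)  # time -> DataFrame

    def significance_flags(self) -> pd.DataFrame:
        """Per-effect stars mirroring *p<0.05 / **p<0.01 convention."""
        tab = self.anova_table.copy()
        p = tab["PR(>F)"]
        tab["flag"] = np.where(p < 0.01, "**", np.where(p < 0.05, "*", ""))
        return tab


def normalized_cfu(table: CFUToxicityTable) -> pd.DataFrame:
    """Per-condition survival ratios relative to the same-time control.

    Returns one row per (concentration, time): the ratio of mean
    treated to mean control CFU, its SD from first-order error
    propagation of the replicate SDs, and the replicate count.
    """
    rows = []
    for t, sub in table.data.groupby("time_h"):
        ctrl = sub.loc[sub["concentration"] == 0, "cfu_count"]
        m_c = ctrl.mean()
        if m_c == 0:
            raise ValueError(f"control mean CFU is zero at time {t} h")
        sd_c = ctrl.std(ddof=1) if len(ctrl) > 1 else 0.0
        for conc, cell in sub.groupby("concentration"):
            counts = cell["cfu_count"]
            m = counts.mean()
            sd = counts.std(ddof=1) if len(counts) > 1 else 0.0
            ratio = m / m_c
            # first-order propagation of the two relative variances
            if m > 0:
                ratio_sd = ratio * math.sqrt((sd / m) ** 2 + (sd_c / m_c) ** 2)
            else:
                ratio_sd = sd / m_c
            rows.append(
                {
                    "concentration": conc,
                    "time_h": t,
                    "ratio": ratio,
                    "ratio_sd": ratio_sd,
                    "n_replicates": len(counts),
                }
            )
    out = pd.DataFrame(rows).sort_values(["concentration", "time_h"])
    return out.reset_index(drop=True)


def minimal_inhibitory_concentration(
    ratios: pd.DataFrame,
    reduction_threshold: float = 0.20,
    significance: AnovaResult | None = None,
    alpha_level: float = 0.05,
):
    """Lowest concentration with a mean CFU reduction beyond the threshold.

    A concentration qualifies when its mean ratio falls below
    ``1 - reduction_threshold`` at any incubation time. When an
    :class:`AnovaResult` is supplied, the drop must additionally be
    Tukey-significant against the concentration-0 control at that time.
    Returns ``None`` when no tested concentration qualifies.
    """
    if len(ratios) == 0:
        raise ValueError("empty ratio table")
    cutoff = 1.0 - reduction_threshold
    for conc in np.sort(ratios["concentration"].unique()):
        if conc == 0:
            continue
        sub = ratios[ratios["concentration"] == conc]
        for _, row in sub.iterrows():
            if row["ratio"] < cutoff:
                if significance is None or _tukey_significant_vs_control(
                    significance, conc, row["time_h"], alpha_level
                ):
                    return conc
    return None


def _tukey_significant_vs_control(
    result: AnovaResult, conc, time_h, alpha_level: float
) -> bool:
    tab = result.tukey_tables.get(time_h)
    if tab is None:
        return False
    pair = tab[
        ((tab["group1"] == 0) & (tab["group2"] == conc))
        | ((tab["group1"] == conc) & (tab["group2"] == 0))
    ]
    return bool(len(pair)) and bool((pair["p_adj"] < alpha_level).any())


def doubling_time(curve: GrowthCurve, window: tuple[float, float] | None = None) -> float:
    """Doubling time (minutes) from the exponential phase of a growth curve.

    Fits log2(OD600) against time by least squares over the window and
    returns 1/slope. With ``window=None`` the exponential phase is
    located automatically: the longest run of consecutive points whose
    local log-slopes are positive and all within 20% of the run's
    median slope.
    """
    t, od = curve.times, curve.od600
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        if np.sum(mask) < 3:
            raise ValueError("window must contain at least 3 points")
        ti, yi = t[mask], np.log2(od[mask])
        if not np.all(np.diff(od[mask]) > 0):
            raise ValueError("OD must be increasing inside the window (no growth)")
    else:
        ti, yi = _auto_exponential_window(t, od)
    slope = np.polyfit(ti, yi, 1)[0]
    if slope <= 0:
        raise ValueError("non-positive growth slope (no growth detected)")
    return float(1.0 / slope)


def _auto_exponential_window(t: np.ndarray, od: np.ndarray):
    y = np.log2(od)
    local = np.diff(y) / np.diff(t)
    n = len(local)
    best: tuple[int, int] | None = None
    # O(n^2) scan over contiguous slope runs; curves are short
    for i in range(n):
        for j in range(i + 2, n):  # >= 3 slopes => >= 4 points
            seg = local[i : j + 1]
            if np.any(seg <= 0):
                continue
            med = np.median(seg)
            if np.all(np.abs(seg - med) <= 0.2 * med):
                if best is None or (j - i) > (best[1] - best[0]):
                    best = (i, j)
    if best is None:
        # fall back to shortest admissible run (2 slopes / 3 points)
        for i in range(n - 1):
            seg = local[i : i + 2]
            med = np.median(seg)
            if np.all(seg > 0) and np.all(np.abs(seg - med) <= 0.2 * med):
                if best is None:
                    best = (i, i + 1)
    if best is None:
        raise ValueError("no exponential growth phase found (no-growth curve)")
    i, j = best
    return t[i : j + 2], y[i : j + 2]


def two_factor_anova(table: CFUToxicityTable) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction, plus Tukey HSD.

    Factors are concentration and incubation time; type-II sums of
    squares accommodate unbalanced cells. Tukey HSD compares
    concentration levels within each incubation time (Tukey-Kramer
    correction applies automatically for unequal group sizes).
    """
    df = table.data.copy()
    for factor in ("concentration", "time_h"):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs at least 2 levels")
    sizes = df.groupby(["concentration", "time_h"]).size()
    if (sizes < 2).any():
        raise ValueError("every concentration x time cell needs >= 2 replicates")
    model = smf.ols(
        "cfu_count ~ C(concentration) * C(time_h)", data=df
    ).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    tukey_tables = {}
    for t, sub in df.groupby("time_h"):
        res = pairwise_tukeyhsd(sub["cfu_count"], sub["concentration"], alpha=0.05)
        tab = pd.DataFrame(
            res.summary().data[1:], columns=[c.replace("-", "_") for c in res.summary().data[0]]
        )
        tab = tab.rename(columns={"p_adj": "p_adj"})
        tab["p_adj"] = res.pvalues
        tab["significant_0.05"] = res.pvalues < 0.05
        tab["significant_0.01"] = res.pvalues < 0.01
        tukey_tables[t] = tab
    return AnovaResult(anova_table=anova, tukey_tables=tukey_tables)
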