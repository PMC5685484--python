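"""Group comparisons and report output.

Comparisons follow the study design: one value per animal (the mean over
its serial sections), classical equal-variance Student's t between
control and treated groups, and a one-sample t against the null ratio of
1 when asking whether a within-section ratio deviates from symmetry.
Two-sided p-values throughout.  Significance stars: * p<0.05, ** p<0.01.

Dispersion is configurable per metric (SEM or SD) because different
readouts are conventionally plotted with different error bars.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps


def stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    test: str  # "two_sample" or "one_sample_vs_1"
    n_control: int
    n_treated: int  # 0 for one-sample tests
    mean_control: float
    mean_treated: float  # the single group's mean for one-sample tests
    t: float
    p: float
    stars: str
    dispersion: str = "SEM"  # convention used when reporting, not in the test

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _finite(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"{name}: need at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: non-finite values")
    return arr


def two_sample_t(control: Sequence[float], treated: Sequence[float],
                 metric: str = "", welch: bool = False) -> GroupComparison:
    """Two-sided two-sample t-test (classical equal-variance Student by default).

    Welch's unequal-variance variant is available behind ``welch=True``.
    Zero pooled variance with equal means yields t = 0, p = 1; with
    unequal means the statistic is infinite and p = 0 (degenerate data).
    """
    c = _finite(control, "control")
    t_ = _finite(treated, "treated")
    if np.var(c, ddof=1) == 0.0 and np.var(t_, ddof=1) == 0.0:
        if c.mean() == t_.mean():
            res_t, res_p = 0.0, 1.0
        else:
            res_t = np.inf if t_.mean() > c.mean() else -np.inf
            res_p = 0.0
    else:
        res = _sps.ttest_ind(c, t_, equal_var=not welch)
        res_t, res_p = float(res.statistic), float(res.pvalue)
    return GroupComparison(metric, "two_sample", c.size, t_.size,
                           float(c.mean()), float(t_.mean()), res_t, res_p, stars(res_p))


def one_sample_t_vs_1(values: Sequence[float], metric: str = "") -> GroupComparison:
    """Two-sided one-sample t-test of a ratio against the null mean of 1."""
    v = _finite(values, "values")
    if np.var(v, ddof=1) == 0.0:
        if v.mean() == 1.0:
            res_t, res_p = 0.0, 1.0
        else:
            res_t = np.inf if v.mean() > 1.0 else -np.inf
            res_p = 0.0
    else:
        res = _sps.ttest_1samp(v, 1.0)
        res_t, res_p = float(res.statistic), float(res.pvalue)
    return GroupComparison(metric, "one_sample_vs_1", v.size, 0,
                           float(v.mean()), float(v.mean()), res_t, res_p, stars(res_p))


def _dispersion(values: np.ndarray, kind: str) -> float:
    sd = float(values.std(ddof=1))
    if kind == "SD":
        return sd
    if kind == "SEM":
        return sd / float(np.sqrt(values.size))
    raise ValueError(f"dispersion must be 'SEM' or 'SD', not {kind!r}")


def compare_ratio_table(
    tidy: pd.DataFrame,
    dispersion: Mapping[str, str] | str = "SEM",
) -> pd.DataFrame:
    """Per-metric control-vs-treated comparison of animal-mean ratios.

    ``tidy`` needs columns ``group, animal_id, metric, animal_mean`` (the
    output of the scoring pipeline or of
    :func:`gyrimetry.synthetic.cohort_ratios`).  Output columns:
    ``metric, n_control, n_treated, mean_c, mean_t, dispersion_c,
    dispersion_t, dispersion_kind, t, p, stars``.
    """
    rows = []
    for metric, grp in tidy.groupby("metric", sort=True):
        per_animal = grp.drop_duplicates(["group", "animal_id"])
        groups = dict(list(per_animal.groupby("group")))
        if "control" not in groups or "treated" not in groups:
            missing = {"control", "treated"} - set(groups)
            raise ValueError(f"metric {metric!r}: empty group(s) {sorted(missing)}")
        c = groups["control"]["animal_mean"].to_numpy(dtype=float)
        t_ = groups["treated"]["animal_mean"].to_numpy(dtype=float)
        kind = dispersion if isinstance(dispersion, str) else dispersion.get(metric, "SEM")
        cmp_ = two_sample_t(c, t_, metric=metric)
        rows.append(
            {
                "metric": metric,
                "n_control": c.size, "n_treated": t_.size,
                "mean_c": c.mean(), "mean_t": t_.mean(),
                "dispersion_c": _dispersion(c, kind), "dispersion_t": _dispersion(t_, kind),
                "dispersion_kind": kind,
                "t": cmp_.t, "p": cmp_.p, "stars": cmp_.stars,
            }
        )
    return pd.DataFrame(rows)


def report(
    tidy: pd.DataFrame,
    out_dir: str | Path,
    dispersion: Mapping[str, str] | str = "SEM",
    make_plots: bool = True,
) -> pd.DataFrame:
    """Write the comparison table and one bar plot per metric.

    Deterministic for fixed inputs: the CSV bytes do not change across
    regenerations.  Returns the comparison table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = compare_ratio_table(tidy, dispersion)
    table.to_csv(out / "comparisons.csv", index=False)

    if make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for row in table.itertuples():
            fig, axis = plt.subplots(figsize=(3.0, 3.5))
            means = [row.mean_c, row.mean_t]
            errs = [row.dispersion_c, row.dispersion_t]
            axis.bar(["control", "treated"], means, yerr=errs, capsize=4,
                     color=["0.7", "0.4"], edgecolor="black")
            axis.axhline(1.0, color="black", lw=0.6, ls=":")
            axis.set_ylabel(f"{row.metric} ratio (EP / contra)")
            axis.set_title(f"{row.metric}  {row.stars}  (p={row.p:.3g})", fontsize=9)
            fig.tight_layout()
            safe = row.metric.replace("/", "_")
            fig.savefig(out / f"{safe}.png", dpi=150)
            plt.close(fig)
    return table
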