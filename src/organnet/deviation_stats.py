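"""Group-level summaries of single-scan deviation matrices.

Covers the extreme-deviation readouts (edges whose |z| exceeds the
Bonferroni-corrected normal critical value), z-distribution density fits, and
the ANOVA + post hoc comparison of per-scan extreme-deviation counts between
experimental groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .perturbation import DeviationMatrix


def z_critical(alpha: float, n_comparisons: int) -> float:
    """Two-sided standard-normal critical value after Bonferroni adjustment.

    With alpha = 0.05 over the 28 unique edges of an 8-organ network this is
    3.12 (2 d.p.), the threshold defining an extreme deviation.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return float(stats.norm.ppf(1.0 - alpha / (2.0 * n_comparisons)))


@dataclass
class ExtremeDeviationSummary:
    """Per-group deviation summaries over a common organ panel.

    ``mean_z`` is the signed across-scan mean z matrix; ``mean_abs_z`` its
    absolute value (the quantity whose mean +/- SD characterizes a group's
    overall deviation).  ``pct_extreme_edge`` is the percentage of the group's
    scans flagged extreme on each edge; ``pct_extreme_organ`` averages an
    organ's edge percentages; ``counts_per_scan`` counts extreme edges per
    scan.
    """

    group: str
    organs: list[str]
    mean_z: np.ndarray
    mean_abs_z: np.ndarray
    pct_extreme_edge: np.ndarray
    pct_extreme_organ: pd.Series
    counts_per_scan: pd.Series
    z_threshold: float
    alpha: float
    n_comparisons: int

    def abs_mean_sd(self) -> tuple[float, float]:
        """Mean and SD over unique edges of |mean z| (population SD)."""
        iu = np.triu_indices(len(self.organs), k=1)
        vals = self.mean_abs_z[iu]
        return float(vals.mean()), float(vals.std())


def summarize_group(
    deviations: list[DeviationMatrix],
    group: str,
    alpha: float = 0.05,
) -> ExtremeDeviationSummary:
    """Summarize a group's deviation matrices against the Bonferroni
    threshold over the network's unique edges."""
    if not deviations:
        raise ValueError("no deviation matrices supplied")
    organs = deviations[0].organs
    for d in deviations:
        if d.organs != organs:
            raise ValueError("inconsistent organ panels across deviation matrices")
    k = len(organs)
    n_edges = k * (k - 1) // 2
    thr = z_critical(alpha, n_edges)
    zs = np.stack([d.z for d in deviations])            # scans x k x k
    extreme = np.abs(zs) > thr
    np.einsum("sii->si", extreme)[:] = False            # ignore diagonal
    mean_z = zs.mean(axis=0)
    pct_edge = 100.0 * extreme.mean(axis=0)
    pct_organ = pd.Series(pct_edge.sum(axis=1) / (k - 1), index=organs)
    iu = np.triu_indices(k, k=1)
    counts = pd.Series(
        extreme[:, iu[0], iu[1]].sum(axis=1),
        index=[d.scan_id for d in deviations],
    )
    return ExtremeDeviationSummary(
        group=group,
        organs=list(organs),
        mean_z=mean_z,
        mean_abs_z=np.abs(mean_z),
        pct_extreme_edge=pct_edge,
        pct_extreme_organ=pct_organ,
        counts_per_scan=counts,
        z_threshold=thr,
        alpha=alpha,
        n_comparisons=n_edges,
    )


@dataclass
class ZDensity:
    """Gaussian-kernel density over pooled edge z-scores, with the moments
    needed to characterize heavy/flat-tailed departures from normality."""

    values: np.ndarray
    mean: float
    sd: float
    excess_kurtosis: float
    _kde: stats.gaussian_kde

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        return self._kde(np.asarray(grid, dtype=float))


def fit_z_density(deviations: list[DeviationMatrix]) -> ZDensity:
    """Kernel density (Silverman bandwidth) over all unique-edge z values
    pooled across scans."""
    if not deviations:
        raise ValueError("no deviation matrices supplied")
    pooled = np.concatenate([d.upper_z() for d in deviations])
    if np.unique(pooled).size < 2:
        raise ValueError("need >= 2 distinct z values for a density fit")
    kde = stats.gaussian_kde(pooled, bw_method="silverman")
    return ZDensity(
        values=pooled,
        mean=float(pooled.mean()),
        sd=float(pooled.std(ddof=1)),
        excess_kurtosis=float(stats.kurtosis(pooled, fisher=True, bias=False)),
        _kde=kde,
    )


@dataclass
class GroupComparison:
    """One-way ANOVA over group counts plus post hoc t-tests vs a control."""

    f_statistic: float
    p_value: float
    groups: list[str]
    posthoc: pd.DataFrame     # columns: group, t, p, p_adjusted


def compare_groups_counts(
    counts_by_group: dict[str, np.ndarray],
    control_group: str | None = None,
    variant: str = "pooled",
    bonferroni: bool = False,
) -> GroupComparison:
    """One-way ANOVA of per-scan extreme-deviation counts across groups, with
    pairwise two-sample t-tests of each group against the control.

    ``variant='pooled'`` uses the classical pooled-variance t-test (default);
    ``'welch'`` drops the equal-variance assumption.  ``bonferroni``
    multiplies post hoc p-values by the number of comparisons.  Groups with
    fewer than 2 scans are excluded with a warning.
    """
    usable = {}
    for g, c in counts_by_group.items():
        c = np.asarray(c, dtype=float)
        if c.size < 2:
            warnings.warn(f"group {g!r} has < 2 scans; excluded from comparison")
            continue
        usable[g] = c
    if len(usable) < 2:
        raise ValueError("need >= 2 groups with >= 2 scans")
    names = list(usable)
    with warnings.catch_warnings():
        # f_oneway warns about precision when groups are (near-)constant,
        # e.g. all-zero extreme counts; the degenerate case is handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        f, p = stats.f_oneway(*usable.values())
    if not np.isfinite(f):      # identical values in every group
        f, p = 0.0, 1.0
    control = control_group if control_group is not None else names[0]
    if control not in usable:
        raise ValueError(f"control group {control!r} not among usable groups")
    rows = []
    tests = [g for g in names if g != control]
    for g in tests:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, tp = stats.ttest_ind(usable[g], usable[control], equal_var=(variant == "pooled"))
        rows.append(
            {
                "group": g,
                "t": float(t),
                "p": float(tp),
                "p_adjusted": min(1.0, float(tp) * len(tests)) if bonferroni else float(tp),
            }
        )
    return GroupComparison(
        f_statistic=float(f),
        p_value=float(p),
        groups=names,
        posthoc=pd.DataFrame(rows, columns=["group", "t", "p", "p_adjusted"]),
    )
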