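"""Two-group differential expression on log2 intensities.

"Dysregulated" features are defined by the volcano-style joint gate
|fold change| >= 2 (inclusive) and unpaired t-test p < 0.05 (strict),
computed feature-by-feature between the control and treated groups.
Benjamini-Hochberg FDR is reported alongside but does not gate the call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lncnet.io import ExpressionMatrix

logger = logging.getLogger("lncnet.diffexp")


def signed_fold_change(mean_log2_control: float, mean_log2_treated: float) -> float:
    """Signed linear fold change from two log2 group means.

    With d = treated - control the result is ``+2**d`` for d >= 0 and
    ``-2**(-d)`` otherwise, so the magnitude is always >= 1 and the sign
    encodes direction ("+2" means doubled, "-2" means halved).
    """
    if not (math.isfinite(mean_log2_control) and math.isfinite(mean_log2_treated)):
        raise ValueError("non-finite log2 mean")
    d = mean_log2_treated - mean_log2_control
    return float(2.0 ** d) if d >= 0 else float(-(2.0 ** (-d)))


def two_sample_t(x, y, variant: str = "student") -> tuple[float, float]:
    """Unpaired two-sample t-test, two-sided.

    ``student`` pools the variance (classical independent t-test, the
    default); ``welch`` uses the Satterthwaite degrees of freedom.  Groups
    with zero variance follow the convention p = 1 when the means are equal
    and p = 0 (flagged in the log) when they differ, where the statistic is
    otherwise undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        logger.warning("zero variance with unequal means: p = 0 by convention")
        t = math.inf if y.mean() > x.mean() else -math.inf
        return t, 0.0
    res = stats.ttest_ind(y, x, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-stable)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DiffExpResult:
    """Full per-feature table, the dysregulated subset, and counts."""

    table: pd.DataFrame
    dysregulated: pd.DataFrame
    n_up: int
    n_down: int
    n_tested: int
    n_excluded: int
    fc_threshold: float
    p_threshold: float


def call_dysregulated(
    matrix: ExpressionMatrix,
    features=None,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    variant: str = "student",
) -> DiffExpResult:
    """Per-feature DE statistics and the volcano filter.

    Parameters
    ----------
    matrix
        Two-group expression matrix (log2 scale).
    features
        Optional feature subset (e.g. the probes of one biotype).
    fc_threshold, p_threshold
        The dysregulation gate: |fold change| >= ``fc_threshold`` AND
        p < ``p_threshold``.  FDR is reported, not gated on.

    Features with any missing value are excluded from testing (logged);
    with 4 samples per group there is no room for imputation.
    """
    sub = matrix.subset(features) if features is not None else matrix
    vals = sub.values
    complete = vals.notna().all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.warning("excluded %d feature(s) with missing values", n_excluded)
    vals = vals[complete]

    c = vals[sub.samples_of("control")].to_numpy(dtype=float)
    t = vals[sub.samples_of("treated")].to_numpy(dtype=float)
    n1, n2 = c.shape[1], t.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")

    mc = c.mean(axis=1)
    mt = t.mean(axis=1)
    d = mt - mc
    fc = np.where(d >= 0, 2.0 ** d, -(2.0 ** (-d)))

    vc = c.var(axis=1, ddof=1)
    vt = t.var(axis=1, ddof=1)
    if variant == "student":
        df = np.full(len(vals), n1 + n2 - 2, dtype=float)
        sp2 = ((n1 - 1) * vc + (n2 - 1) * vt) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif variant == "welch":
        a, b = vc / n1, vt / n2
        se = np.sqrt(a + b)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (a + b) ** 2 / (a ** 2 / (n1 - 1) + b ** 2 / (n2 - 1))
    else:
        raise ValueError(f"unknown variant {variant!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = d / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
    # zero-variance conventions (constant features, zero-noise simulations)
    degenerate = se == 0.0
    if degenerate.any():
        eq = degenerate & (d == 0.0)
        ne = degenerate & (d != 0.0)
        tstat[eq], p[eq] = 0.0, 1.0
        tstat[ne] = np.sign(d[ne]) * np.inf
        p[ne] = 0.0
        if ne.any():
            logger.warning(
                "%d feature(s) with zero variance and unequal means: p = 0 by convention",
                int(ne.sum()),
            )

    table = pd.DataFrame(
        {
            "feature_id": vals.index,
            "mean_log2_control": mc,
            "mean_log2_treated": mt,
            "fold_change": fc,
            "direction": np.where(fc > 0, "up", "down"),
            "t": tstat,
            "p_value": p,
            "fdr": benjamini_hochberg(p),
        }
    ).reset_index(drop=True)

    mask = (np.abs(table["fold_change"]) >= fc_threshold) & (table["p_value"] < p_threshold)
    dys = table[mask].reset_index(drop=True)
    n_up = int((dys["direction"] == "up").sum())
    n_down = int((dys["direction"] == "down").sum())
    logger.info(
        "tested %d features: %d up, %d down at |FC|>=%g, p<%g",
        len(table), n_up, n_down, fc_threshold, p_threshold,
    )
    return DiffExpResult(
        table=table,
        dysregulated=dys,
        n_up=n_up,
        n_down=n_down,
        n_tested=len(table),
        n_excluded=n_excluded,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
    )


def group_profile_correlation(matrix: ExpressionMatrix, features=None) -> float:
    """Pearson r between per-feature control means and treated means.

    This is the scatter-plot consistency statistic: close to 1 when the two
    group profiles agree for all but a minor dysregulated fraction.
    """
    sub = matrix.subset(features) if features is not None else matrix
    vals = sub.values.dropna()
    if len(vals) < 2:
        raise ValueError("need at least 2 features")
    mc = vals[sub.samples_of("control")].mean(axis=1)
    mt = vals[sub.samples_of("treated")].mean(axis=1)
    return float(stats.pearsonr(mc, mt).statistic)
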