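"""Validation-arm statistics: 2^-ddCt relative quantification and the
exact Mann-Whitney U test.

RT-qPCR quantification follows the Livak convention: per sample
dCt = target Ct - reference Ct (endogenous control, e.g. Actb);
ddCt = dCt - mean control-group dCt; relative expression = 2^-ddCt.
Group comparison at n = 4 per group uses the exact, tie-aware
Mann-Whitney U test (normal approximation available by flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CtRecord:
    """One sample's mean qPCR cycle thresholds (triplicate means)."""

    sample_id: str
    group: str
    target_ct: float
    reference_ct: float

    def __post_init__(self) -> None:
        for v in (self.target_ct, self.reference_ct):
            if not (math.isfinite(v) and v > 0):
                raise ValueError("cycle thresholds must be positive and finite")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


def ddct_relative_expression(case: CtRecord, control_mean_dct: float) -> float:
    """Linear fold change of one sample relative to the control baseline."""
    if not math.isfinite(control_mean_dct):
        raise ValueError("non-finite control baseline")
    ddct = case.delta_ct - control_mean_dct
    return float(2.0 ** (-ddct))


def mann_whitney_exact(x, y, method: str = "exact") -> tuple[float, float]:
    """Mann-Whitney U with exact two-sided p by enumeration.

    The U statistic uses midranks for ties.  The exact p enumerates all
    C(n1+n2, n1) assignments of the pooled (midranked) values to groups -
    a tie-aware permutation null - and counts assignments at least as
    extreme as observed in |U - n1*n2/2|.  ``method="normal"`` switches to
    the tie-corrected normal approximation for larger samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    if method == "normal":
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic").pvalue)
        return float(u), p
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    if n1 + n2 > 16:
        raise ValueError("exact enumeration limited to combined n <= 16; "
                         "use method='normal'")

    mu = n1 * n2 / 2.0
    obs = abs(u - mu)
    total = 0
    extreme = 0
    eps = 1e-9
    for idx in combinations(range(n1 + n2), n1):
        u_perm = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u_perm - mu) >= obs - eps:
            extreme += 1
    return float(u), extreme / total


def relative_expression_table(
    ct: pd.DataFrame, method: str = "exact"
) -> pd.DataFrame:
    """Per-gene relative expression and group comparison from a Ct table.

    ``ct`` columns: sample_id, group (control/treated), gene, target_ct,
    reference_ct.  Returns one row per gene with the group mean fold
    changes (2^-ddCt, control baseline) and the Mann-Whitney p between the
    per-sample fold changes of the two groups.
    """
    required = {"sample_id", "group", "gene", "target_ct", "reference_ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    rows = []
    for gene, sub in ct.groupby("gene", sort=True):
        dct = sub["target_ct"] - sub["reference_ct"]
        is_ctrl = sub["group"] == "control"
        if not is_ctrl.any() or is_ctrl.all():
            raise ValueError(f"gene {gene!r}: need both groups")
        baseline = dct[is_ctrl].mean()
        fold = 2.0 ** (-(dct - baseline))
        fc_ctrl = fold[is_ctrl].to_numpy()
        fc_trt = fold[~is_ctrl].to_numpy()
        u, p = mann_whitney_exact(fc_ctrl, fc_trt, method=method)
        rows.append(
            {
                "gene": gene,
                "mean_fold_control": float(fc_ctrl.mean()),
                "mean_fold_treated": float(fc_trt.mean()),
                "U": u,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
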