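"""Screen quality metrics: assay window (Z'-factor) and control statistics.

The Z'-factor, ``1 - 3 (sigma_p + sigma_n) / |mu_p - mu_n|``, summarizes how
well a screening assay separates its positive and negative controls: 1 is a
perfect (zero-variance) assay, values above ~0.5 indicate a robust screen,
and values at or below 0 mean the control distributions overlap.  It can
never exceed 1 and is invariant under common affine rescaling of both
control groups.

Control behavior across plates is compared to the per-plate screen average
with two-sample t-tests (Welch by default — no equal-variance assumption,
Satterthwaite degrees of freedom; a paired-by-plate variant is available).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientReplicationError, UndefinedWindowError
from .screen_io import COLUMN_LABELS, ScreenMatrix


def z_prime_factor(positive_values, negative_values) -> float:
    """Assay-window statistic of positive vs negative control values.

    Uses sample standard deviations (ddof=1).  Raises
    :class:`UndefinedWindowError` when the group means coincide (zero assay
    window).
    """
    pos = np.asarray(list(positive_values), dtype=float)
    neg = np.asarray(list(negative_values), dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise InsufficientReplicationError("need >= 2 values per control group")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    if mu_p == mu_n:
        raise UndefinedWindowError("control means coincide; assay window undefined")
    sd_p, sd_n = float(pos.std(ddof=1)), float(neg.std(ddof=1))
    return 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)


def welch_ttest(a, b) -> tuple[float, float, float]:
    """Two-sided Welch two-sample t-test.

    Returns ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom.  Two
    numerically identical groups give ``t = 0, p = 1`` by convention (zero
    difference over zero spread difference is no evidence of a difference).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicationError("need >= 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0:
        # degenerate: both groups constant
        if diff == 0:
            return 0.0, float(na + nb - 2), 1.0
        return math_inf_sign(diff), float(na + nb - 2), 0.0
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def math_inf_sign(x: float) -> float:
    return float("inf") if x > 0 else float("-inf")


def paired_ttest(a, b) -> tuple[float, float, float]:
    """Two-sided paired t-test on per-plate pairs (a_i, b_i)."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size != b.size:
        raise InsufficientReplicationError("paired test needs equal-length groups")
    if a.size < 2:
        raise InsufficientReplicationError("need >= 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        return (0.0, float(a.size - 1), 1.0) if d.mean() == 0 else (
            math_inf_sign(d.mean()),
            float(a.size - 1),
            0.0,
        )
    t = d.mean() / (sd / np.sqrt(a.size))
    df = float(a.size - 1)
    return float(t), df, float(2.0 * stats.t.sf(abs(t), df))


def plate_summaries(
    matrix: ScreenMatrix, plates: pd.Series
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-plate control means and per-plate screen (library) averages.

    Parameters
    ----------
    matrix : ScreenMatrix
        Normalized screen values with role annotations.
    plates : Series
        Gene -> plate id for every gene in the matrix.

    Returns
    -------
    (control_means, screen_averages)
        ``control_means`` maps each control role to a plate x condition
        DataFrame of mean normalized expression; ``screen_averages`` is the
        plate x condition mean over library entries.
    """
    plates = plates.reindex(matrix.values.index)
    lib = matrix.roles == "library"
    screen_avg = (
        matrix.values.loc[lib].groupby(plates.loc[lib]).mean().sort_index()
    )
    control_means: dict[str, pd.DataFrame] = {}
    for role in ("nontargeting_control", "tp53_control", "mdm2_control"):
        sel = matrix.roles == role
        if sel.any():
            control_means[role] = (
                matrix.values.loc[sel].groupby(plates.loc[sel]).mean().sort_index()
            )
    return control_means, screen_avg


def control_vs_average_tests(
    control_means: dict[str, pd.DataFrame],
    screen_averages: pd.DataFrame,
    paired: bool = False,
) -> pd.DataFrame:
    """t-tests of per-plate control means against per-plate screen averages.

    One test per control role per condition; Welch (unpaired, unequal
    variance) by default, paired-by-plate when ``paired``.  Returns a tidy
    DataFrame with columns role, condition, t, df, p.
    """
    rows = []
    for role, ctl in control_means.items():
        for col in COLUMN_LABELS:
            if col not in ctl.columns or col not in screen_averages.columns:
                continue
            a = ctl[col].dropna()
            b = screen_averages[col].dropna()
            if a.size < 2 or b.size < 2:
                raise InsufficientReplicationError(
                    f"{role}/{col}: need >= 2 plates per group"
                )
            if paired:
                common = a.index.intersection(b.index)
                t, df, p = paired_ttest(a.loc[common], b.loc[common])
            else:
                t, df, p = welch_ttest(a, b)
            rows.append((role, col, t, df, p))
    return pd.DataFrame(rows, columns=["role", "condition", "t", "df", "p"])


def qc_report(
    matrix: ScreenMatrix,
    plates: pd.Series,
    positive_role: str = "tp53_control",
    negative_role: str = "nontargeting_control",
    paired: bool = False,
) -> dict:
    """Assemble the screen QC bundle: per-condition Z' plus control t-tests.

    The Z'-factor per condition contrasts individual control-well values of
    ``positive_role`` against ``negative_role``.
    """
    control_means, screen_avg = plate_summaries(matrix, plates)
    z_prime: dict[str, float] = {}
    pos = matrix.values.loc[matrix.roles == positive_role]
    neg = matrix.values.loc[matrix.roles == negative_role]
    for col in COLUMN_LABELS:
        p, n = pos[col].dropna(), neg[col].dropna()
        if p.size >= 2 and n.size >= 2:
            try:
                z_prime[col] = z_prime_factor(p, n)
            except UndefinedWindowError:
                z_prime[col] = float("nan")
    tests = control_vs_average_tests(control_means, screen_avg, paired=paired)
    return {
        "z_prime": z_prime,
        "ttest_results": tests,
        "control_plate_means": control_means,
        "screen_plate_averages": screen_avg,
    }
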