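"""Statistical battery for metrics tables.

Normality-screened two-sample comparisons (Shapiro-Wilk gate choosing
between t tests and Wilcoxon tests), two-way mixed repeated-measures ANOVA,
and Benjamini-Hochberg step-up FDR adjustment. The comparison and ANOVA
routines delegate the heavy lifting to scipy/pingouin; this module owns the
branch logic, the balanced-design guard, and the result container.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TestResult", "bh_fdr", "compare_groups", "mixed_rm_anova"]


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: Optional[tuple] = None
    n: Optional[tuple] = None
    adjusted_p: Optional[float] = None
    effect: Optional[str] = None


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    With m p-values sorted ascending, ``adj_(i) = min_{j >= i} m * p_(j) / j``
    clipped at 1; adjusted values are monotone non-decreasing in sorted
    order and never smaller than the raw values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def compare_groups(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
    normality_alpha: float = 0.05,
) -> TestResult:
    """Two-sample comparison with a Shapiro-Wilk normality gate.

    Both samples pass Shapiro-Wilk at ``normality_alpha`` -> t test (paired
    or independent); otherwise the Wilcoxon signed-rank (paired) or
    rank-sum (independent) test. ``test_name`` records which branch fired.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per sample")
    if paired and len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    normal = (sps.shapiro(x).pvalue > normality_alpha
              and sps.shapiro(y).pvalue > normality_alpha)
    if normal:
        if paired:
            res = sps.ttest_rel(x, y)
            name = "paired t test"
            df = (len(x) - 1,)
        else:
            res = sps.ttest_ind(x, y)
            name = "t test"
            df = (len(x) + len(y) - 2,)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if paired:
            if np.allclose(x, y):
                # Degenerate signed-rank input (all differences zero).
                stat, p, name, df = 0.0, 1.0, "Wilcoxon signed-rank", None
            else:
                res = sps.wilcoxon(x, y)
                stat, p = float(res.statistic), float(res.pvalue)
                name, df = "Wilcoxon signed-rank", None
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
            name, df = "Wilcoxon rank-sum", None
    return TestResult(test_name=name, statistic=stat, p_value=p, df=df,
                      n=(len(x), len(y)))


def _check_balanced(table: pd.DataFrame, subject: str, within: List[str],
                    between: Optional[str]) -> None:
    if between is not None:
        per_subj = table.groupby(subject)[between].nunique()
        if (per_subj > 1).any():
            bad = per_subj[per_subj > 1].index.tolist()
            raise ValueError(f"subjects in multiple between-levels: {bad}")
    counts = table.groupby([subject, *within]).size()
    expected = (
        table[subject].nunique()
        * int(np.prod([table[w].nunique() for w in within]))
    )
    if counts.size != expected or counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: every subject needs exactly one observation "
            "per within-factor cell (no silent imputation)"
        )


def mixed_rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str,
    between: Optional[str] = None,
    correction: bool = False,
) -> List[TestResult]:
    """Mixed / repeated-measures ANOVA on a long-format table.

    Supported designs: one between-subjects factor with one within factor
    (mixed), or one or two within factors with no between factor (pure
    repeated measures, e.g. dose x time). Greenhouse-Geisser correction is
    optional and off by default. Returns one TestResult per effect
    (main effects and interaction), labelled e.g. ``dose``, ``time``,
    ``dose * time``.
    """
    import pingouin as pg

    within = list(within)
    if not within:
        raise ValueError("at least one within-subject factor required")
    for col in [dv, subject, *within] + ([between] if between else []):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from table")
    for w in within:
        if table[w].nunique() < 2:
            raise ValueError(f"within factor {w!r} needs >= 2 levels")
    _check_balanced(table, subject, within, between)

    if between is not None:
        if len(within) != 1:
            raise ValueError(
                "a between factor is supported with exactly one within "
                "factor; use a pure within design for dose x time"
            )
        aov = pg.mixed_anova(data=table, dv=dv, within=within[0],
                             subject=subject, between=between,
                             correction=correction)
    else:
        if len(within) > 2:
            raise ValueError("at most two within factors supported")
        aov = pg.rm_anova(data=table, dv=dv, within=within,
                          subject=subject, correction=correction,
                          detailed=True)

    results = []
    for _, row in aov.iterrows():
        label = str(row["Source"])
        if label in ("Residual", "Error"):
            continue
        unc = next(c for c in ("p_unc", "p-unc") if c in aov.columns)
        p_col = unc
        if correction:
            gg = next((c for c in ("p_GG_corr", "p-GG-corr")
                       if c in aov.columns), None)
            if gg is not None and pd.notna(row.get(gg)):
                p_col = gg
        df1 = row.get("ddof1", row.get("DF1", row.get("DF")))
        df2 = row.get("ddof2", row.get("DF2"))
        if pd.isna(row.get("F")):
            continue
        results.append(TestResult(
            test_name="mixed RM-ANOVA" if between else "RM-ANOVA",
            statistic=float(row["F"]),
            p_value=float(row[p_col]),
            df=(None if pd.isna(df1) else float(df1),
                None if df2 is None or pd.isna(df2) else float(df2)),
            effect=label,
        ))
    return results
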