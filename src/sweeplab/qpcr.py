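"""Relative expression by the 2^-ddCt method and its rank test.

Input is a long-format Ct table with columns (sample, line, gene, ct)
where gene is "target" or "reference" and replicate wells appear as
separate rows.  Replicate Cts are averaged per (sample, gene); per sample
dCt = mean Ct_target - mean Ct_reference; ddCt subtracts the calibrator
line's mean dCt; fold change is 2^-ddCt.  The line summary reports both
the fold from line-mean dCt and the mean of per-sample folds, since the
two conventions differ.  PCR-efficiency correction is deliberately
omitted (plain 2^-ddCt).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["relative_expression", "mann_whitney_u", "read_ct_table"]

REQUIRED_COLUMNS = ("sample", "line", "gene", "ct")


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns: {missing}")
    return df


def relative_expression(ct: pd.DataFrame, calibrator_line: str
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample fold changes and per-line summaries.

    Samples missing either gene are dropped with a warning.  Returns
    (per_sample, per_line); per_line carries ``fold_line_mean``
    (2^-(mean dCt_line - mean dCt_calibrator)) and ``fold_mean_of_samples``.
    """
    for col in REQUIRED_COLUMNS:
        if col not in ct.columns:
            raise ValueError(f"Ct table lacks column {col!r}")
    if calibrator_line not in set(ct["line"]):
        raise ValueError(f"calibrator line {calibrator_line!r} not present")
    means = (ct.groupby(["sample", "line", "gene"])["ct"].mean()
             .unstack("gene"))
    for gene in ("target", "reference"):
        if gene not in means.columns:
            raise ValueError(f"no rows with gene == {gene!r}")
    incomplete = means[means[["target", "reference"]].isna().any(axis=1)]
    if not incomplete.empty:
        warnings.warn(f"dropping samples missing a gene: "
                      f"{[s for s, _ in incomplete.index]}")
        means = means.drop(incomplete.index)
    per_sample = means.reset_index()
    per_sample["dct"] = per_sample["target"] - per_sample["reference"]
    cal_mean = per_sample.loc[per_sample["line"] == calibrator_line, "dct"].mean()
    per_sample["ddct"] = per_sample["dct"] - cal_mean
    per_sample["fold"] = 2.0 ** (-per_sample["ddct"])
    per_line = per_sample.groupby("line").agg(
        n=("sample", "size"), mean_dct=("dct", "mean"),
        fold_mean_of_samples=("fold", "mean"))
    per_line["fold_line_mean"] = 2.0 ** (-(per_line["mean_dct"] - cal_mean))
    return per_sample, per_line.reset_index()


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact null distribution when both groups have at most 8 observations
    and no cross-group ties; otherwise the tie-corrected normal
    approximation.  Entirely tied data yield p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
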