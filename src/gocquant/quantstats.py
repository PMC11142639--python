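"""Summary statistics of the study: EdU fractions, 2^(−ΔΔCt), percent
change, group summaries, and one-/two-sample two-tailed t-tests.

Conventions follow the source assays:

* groups are reported as mean ± SEM (sample SD, ddof=1, over √n);
* percent change is ``100·(mean_ref − mean_test)/mean_ref`` — positive for a
  *reduction* relative to the reference group, the direction in which the
  effects of interest are phrased;
* relative qPCR expression uses the 2^(−ΔΔCt) method with a reference gene
  (``Rpl19``) and a calibrator group;
* the default two-sample test is Student's (pooled variance); Welch is
  available by flag. No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "EffectReport",
    "edu_fraction",
    "ddct_fold_change",
    "percent_change",
    "t_test",
    "summarize_group",
]


@dataclass
class GroupSummary:
    """Mean ± SEM of one group. SEM is NaN (undefined) for n = 1."""

    label: str
    n: int
    mean: float
    sem: float

    def as_record(self) -> dict:
        return {"label": self.label, "n": self.n, "mean": self.mean, "sem": self.sem}


@dataclass
class EffectReport:
    """A group comparison: percent change plus the t-test that judged it."""

    percent_change: float
    t: float
    df: float
    p: float
    test: str          # "one_sample" | "two_sample"
    variant: str = "student"

    def as_record(self) -> dict:
        return {"percent_change": self.percent_change, "t": self.t,
                "df": self.df, "p": self.p, "test": self.test,
                "variant": self.variant}


def edu_fraction(n_positive: int, n_total: int) -> float:
    """Fraction of EdU-labelled cells among all DAPI-counterstained cells."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_positive <= n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    return n_positive / n_total


def percent_change(mean_ref: float, mean_test: float) -> float:
    """Percent change of ``mean_test`` relative to ``mean_ref``.

    Returns ``100·(mean_ref − mean_test)/mean_ref``: positive for a
    reduction, negative for an increase.
    """
    if mean_ref == 0:
        raise ValueError("reference mean must be non-zero")
    return 100.0 * (mean_ref - mean_test) / mean_ref


def summarize_group(values, label: str = "") -> GroupSummary:
    """Mean and SEM (sample SD / √n) of one group; SEM is NaN when n = 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty group")
    n = values.size
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return GroupSummary(label=label, n=n, mean=mean, sem=sem)


def t_test(
    group_a,
    group_b=None,
    kind: str = "two_sample",
    mu0: float | None = None,
    variant: str = "student",
) -> EffectReport:
    """One- or two-sample two-tailed t-test plus the percent change.

    ``kind="two_sample"``: compares ``group_a`` (reference) against
    ``group_b``; ``variant`` selects Student (pooled variance, default) or
    Welch. ``kind="one_sample"``: tests ``group_a`` against ``mu0`` (used
    for normalized ratios tested against 1).

    Degenerate zero-variance data with equal means is reported as t = 0,
    p = 1 rather than NaN.
    """
    a = np.asarray(group_a, dtype=float)
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if kind == "one_sample":
        if mu0 is None:
            raise ValueError("one_sample test requires mu0")
        if a.size < 2:
            raise ValueError("one_sample test requires n >= 2")
        df = float(a.size - 1)
        if a.var(ddof=1) == 0.0:
            if a.mean() == mu0:
                t, p = 0.0, 1.0
            else:
                t = float(np.sign(a.mean() - mu0)) * float("inf")
                p = 0.0
        else:
            res = sps.ttest_1samp(a, popmean=mu0)
            t, p = float(res.statistic), float(res.pvalue)
        change = percent_change(mu0, float(a.mean())) if mu0 != 0 else float("nan")
        return EffectReport(percent_change=change, t=t, df=df, p=p,
                            test="one_sample", variant="student")
    if kind != "two_sample":
        raise ValueError(f"unknown test kind {kind!r}")
    if group_b is None:
        raise ValueError("two_sample test requires a second group")
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("two_sample test requires n >= 2 per group")
    equal_var = variant == "student"
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # degenerate constant groups: define the outcome instead of NaN
        df = float(a.size + b.size - 2) if equal_var else float("nan")
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = float(np.sign(a.mean() - b.mean())) * float("inf")
            p = 0.0
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    change = percent_change(float(a.mean()), float(b.mean())) if a.mean() != 0 else float("nan")
    return EffectReport(percent_change=change, t=t, df=df, p=p,
                        test="two_sample", variant=variant)


def ddct_fold_change(
    table: pd.DataFrame,
    reference_gene: str = "Rpl19",
    calibrator_group: str | None = None,
    sample_col: str = "sample_id",
    gene_col: str = "gene",
    ct_col: str = "Ct",
    group_col: str = "group",
) -> pd.DataFrame:
    """Relative expression by the 2^(−ΔΔCt) method.

    Per sample and target gene: ΔCt = Ct_gene − Ct_reference; ΔΔCt = ΔCt −
    mean ΔCt of that gene in the calibrator group; fold = 2^(−ΔΔCt). The
    calibrator group's fold changes therefore have geometric mean 1 per
    gene.

    ``table`` needs columns ``sample_id, gene, Ct, group`` (names
    configurable). Every sample must include a reference-gene Ct.
    """
    required = {sample_col, gene_col, ct_col, group_col}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns {sorted(missing)}")
    if (table[ct_col] <= 0).any():
        raise ValueError("Ct values must be > 0 cycles")
    ref = (table[table[gene_col] == reference_gene]
           .set_index(sample_col)[ct_col])
    if ref.index.has_duplicates:
        raise ValueError("multiple reference-gene rows for one sample")
    targets = table[table[gene_col] != reference_gene].copy()
    unmatched = set(targets[sample_col]) - set(ref.index)
    if unmatched:
        raise ValueError(
            f"samples missing reference gene {reference_gene!r}: {sorted(unmatched)}")
    targets["delta_ct"] = targets[ct_col].to_numpy() - ref.loc[targets[sample_col]].to_numpy()
    if calibrator_group is None:
        calibrator_group = targets[group_col].iloc[0]
    cal = targets[targets[group_col] == calibrator_group]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} is empty")
    cal_mean = cal.groupby(gene_col)["delta_ct"].mean()
    genes_without_cal = set(targets[gene_col]) - set(cal_mean.index)
    if genes_without_cal:
        raise ValueError(
            f"genes absent from calibrator group: {sorted(genes_without_cal)}")
    targets["delta_delta_ct"] = (targets["delta_ct"].to_numpy()
                                 - cal_mean.loc[targets[gene_col]].to_numpy())
    targets["fold_change"] = 2.0 ** (-targets["delta_delta_ct"])
    return targets[[sample_col, gene_col, group_col,
                    "delta_ct", "delta_delta_ct", "fold_change"]].reset_index(drop=True)
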