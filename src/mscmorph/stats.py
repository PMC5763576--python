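"""The aging-statistics workflow for morphometric cell tables.

Order of operations mirrors the analysis the pipeline automates:

1. per-variable two-tail trimming of artificial outliers (5%/5% default);
2. Box-Cox transformation (log for most variables; λ=2 for the two
   left-skewed ratios) to bring distributions near normal;
3. per-group (donor×passage) summaries with skewness diagnostics;
4. ranking of linear models PD ~ summary(variable) by R²;
5. two-way ANOVA (donor, passage, interaction; Type II sums of squares
   for the unbalanced design) with Bonferroni-corrected pairwise t tests
   gated on ANOVA significance;
6. two-sample Kolmogorov–Smirnov comparisons against a reference passage
   (invariant under monotone transforms, so raw and log data give the
   same D and p);
7. the fold-change table of group means against the reference passage.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TrimSpec",
    "TransformSpec",
    "DEFAULT_TRANSFORMS",
    "trim_outliers",
    "box_cox",
    "group_skewness",
    "rank_pd_models",
    "anova_two_way",
    "pairwise_bonferroni",
    "ks_between_passages",
    "fold_change_table",
]


@dataclass(frozen=True)
class TrimSpec:
    """Two-tail trim fractions for one variable."""

    lower_fraction: float = 0.05
    upper_fraction: float = 0.05
    variable: str = "area"

    def __post_init__(self) -> None:
        if self.lower_fraction < 0 or self.upper_fraction < 0:
            raise ValueError("trim fractions must be nonnegative")
        if self.lower_fraction + self.upper_fraction >= 1:
            raise ValueError("trim fractions must sum to less than 1")


@dataclass(frozen=True)
class TransformSpec:
    """Box-Cox parameter for one variable."""

    variable: str
    lam: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.lam):
            raise ValueError("lambda must be finite")


#: λ per descriptor: log for the right-skewed variables, λ=2 for the two
#: left-skewed ratios (boxed frame ratio, convex hull perimeter ratio).
DEFAULT_TRANSFORMS = {
    "length": 0.0,
    "width": 0.0,
    "area": 0.0,
    "perimeter": 0.0,
    "perimeter_area_ratio": 0.0,
    "length_width_ratio": 0.0,
    "boxed_frame_ratio": 2.0,
    "convex_hull_area_ratio": 0.0,
    "convex_hull_perimeter_ratio": 2.0,
}


def trim_outliers(values, spec: TrimSpec = TrimSpec()):
    """Drop the ``floor(f_lo*N)`` smallest and ``floor(f_hi*N)`` largest values.

    Ties are broken by stable input order and the retained values keep
    their original order.  Returns a numpy array (or, for a DataFrame
    input via :func:`trim_table`, see there).
    """
    values = np.asarray(values)
    n = values.size
    if n == 0:
        raise ValueError("cannot trim an empty list")
    k_lo = int(np.floor(spec.lower_fraction * n))
    k_hi = int(np.floor(spec.upper_fraction * n))
    if k_lo + k_hi >= n:
        raise ValueError(f"trimming {k_lo}+{k_hi} values would empty a list of {n}")
    order = np.argsort(values, kind="stable")
    drop = np.concatenate([order[:k_lo], order[n - k_hi :] if k_hi else order[:0]])
    keep = np.ones(n, dtype=bool)
    keep[drop] = False
    return values[keep]


def trim_table(
    records: pd.DataFrame, variable: str, spec: TrimSpec | None = None
) -> pd.DataFrame:
    """Per-variable trimming of a cell table: rows in the tails of
    ``variable`` are dropped, everything else is untouched."""
    spec = spec or TrimSpec(variable=variable)
    values = records[variable].to_numpy()
    n = values.size
    k_lo = int(np.floor(spec.lower_fraction * n))
    k_hi = int(np.floor(spec.upper_fraction * n))
    if k_lo + k_hi >= n:
        raise ValueError("trimming would empty the table")
    order = np.argsort(values, kind="stable")
    drop = np.concatenate([order[:k_lo], order[n - k_hi :] if k_hi else order[:0]])
    keep = np.ones(n, dtype=bool)
    keep[drop] = False
    return records.iloc[keep].reset_index(drop=True)


def box_cox(values, spec: TransformSpec):
    """Box-Cox power transform: ``(y**λ - 1)/λ``, or ``ln(y)`` at λ=0."""
    y = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(y > 0))
    if bad.size:
        raise ValueError(
            f"Box-Cox requires positive values; first offending index {bad[0]} "
            f"(value {y[bad[0]]!r})"
        )
    if spec.lam == 0.0:
        return np.log(y)
    return (y**spec.lam - 1.0) / spec.lam


def _skew(x: np.ndarray) -> tuple[float, bool]:
    """Adjusted Fisher–Pearson sample skewness; constants give 0, flagged."""
    if np.ptp(x) == 0:
        return 0.0, True
    return float(sps.skew(x, bias=False)), False


def group_skewness(
    records: pd.DataFrame,
    variable: str,
    transform: TransformSpec | None = None,
    group_cols: tuple[str, str] = ("donor", "passage"),
) -> pd.DataFrame:
    """Per donor×passage summaries before and after the transform.

    Columns: group identifiers, n, raw_mean/raw_sd/raw_skewness, and
    mean/sd/skewness on the transformed scale.  Groups with fewer than
    three cells are skipped with a warning.
    """
    transform = transform or TransformSpec(variable, DEFAULT_TRANSFORMS.get(variable, 0.0))
    rows = []
    for keys, sub in records.groupby(list(group_cols), observed=True, sort=True):
        x = sub[variable].to_numpy(dtype=float)
        if x.size < 3:
            warnings.warn(
                f"group {keys}: n={x.size} < 3, skipped for {variable}", stacklevel=2
            )
            continue
        t = box_cox(x, transform)
        raw_skew, raw_deg = _skew(x)
        t_skew, t_deg = _skew(t)
        rows.append(
            {
                group_cols[0]: keys[0],
                group_cols[1]: keys[1],
                "variable": variable,
                "n": x.size,
                "raw_mean": float(x.mean()),
                "raw_sd": float(x.std(ddof=1)),
                "raw_skewness": raw_skew,
                "mean": float(t.mean()),
                "sd": float(t.std(ddof=1)),
                "skewness": t_skew,
                "degenerate": raw_deg or t_deg,
            }
        )
    return pd.DataFrame(rows)


def rank_pd_models(summaries: pd.DataFrame, pd_table: pd.DataFrame) -> pd.DataFrame:
    """OLS fits of PD on each (variable, summary kind) pair, ranked by R².

    ``summaries`` is the output of :func:`group_skewness` (possibly
    concatenated over variables); ``pd_table`` maps donor×passage to a
    PD value.  Both the group mean and the group SD of each transformed
    variable are tried as the explanatory variable.  Constant
    explanatory variables are skipped with a warning.  Ties in R² are
    broken alphabetically by (variable, kind).
    """
    merged = summaries.merge(pd_table, on=["donor", "passage"], how="inner")
    if merged["pd"].notna().sum() < 3 or merged.groupby(["donor", "passage"]).ngroups < 3:
        raise ValueError("need at least 3 donor/passage groups with PD values")
    fits = []
    for variable, sub in merged.groupby("variable", sort=True):
        for kind, col in (("mean", "mean"), ("sd", "sd")):
            x = sub[col].to_numpy(dtype=float)
            y = sub["pd"].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                warnings.warn(
                    f"{variable}/{kind}: constant explanatory variable, fit skipped",
                    stacklevel=2,
                )
                continue
            res = sps.linregress(x, y)
            fits.append(
                {
                    "variable": variable,
                    "summary_kind": kind,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "r_squared": res.rvalue**2,
                    "n_groups": x.size,
                }
            )
    out = pd.DataFrame(fits)
    if out.empty:
        return out
    out = out.sort_values(
        ["r_squared", "variable", "summary_kind"], ascending=[False, True, True]
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def anova_two_way(
    records: pd.DataFrame,
    variable: str,
    transform: TransformSpec | None = None,
    factors: tuple[str, str] = ("donor", "passage"),
) -> pd.DataFrame:
    """Two-way ANOVA (factors + interaction) on the transformed variable.

    Type II sums of squares accommodate the unbalanced donor×passage
    design (the senescent passage is often missing a donor).  Every
    donor×passage cell must be populated, and interaction estimation
    requires at least one cell with replication.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    transform = transform or TransformSpec(variable, DEFAULT_TRANSFORMS.get(variable, 0.0))
    a, b = factors
    if records[a].nunique() < 2 or records[b].nunique() < 2:
        raise ValueError("two-way ANOVA needs >= 2 levels of each factor")
    counts = records.groupby([a, b], observed=True).size()
    full = pd.MultiIndex.from_product([records[a].unique(), records[b].unique()])
    missing = full.difference(counts.index)
    if len(missing):
        raise ValueError(f"empty design cell for {a}/{b} pair {tuple(missing[0])}")
    if (counts < 2).all():
        raise ValueError(
            "no replication within design cells; the interaction is unidentifiable"
        )
    df = records[[a, b]].copy()
    df["y"] = box_cox(records[variable].to_numpy(dtype=float), transform)
    model = smf.ols(f"y ~ C({a}) * C({b})", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            f"C({a})": a,
            f"C({b})": b,
            f"C({a}):C({b})": f"{a}:{b}",
            "Residual": "residual",
        }
    )
    table.index.name = "effect"
    return table.reset_index().rename(columns={"PR(>F)": "p_value"})


def pairwise_bonferroni(
    records: pd.DataFrame,
    variable: str,
    grouping: str,
    transform: TransformSpec | None = None,
    anova_p: float | None = None,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """All pairwise t tests between groups, Bonferroni corrected.

    The tests are gated on the overall ANOVA being significant: pass the
    ANOVA p-value as ``anova_p``; if it exceeds ``alpha`` a not-run
    report (empty, attrs['run']=False) is returned.  Welch's t test is
    the default (group variances grow strongly with passage).
    """
    transform = transform or TransformSpec(variable, DEFAULT_TRANSFORMS.get(variable, 0.0))
    if anova_p is not None and anova_p > alpha:
        out = pd.DataFrame(
            columns=["group_a", "group_b", "t", "p_raw", "p_adjusted", "n_comparisons"]
        )
        out.attrs["run"] = False
        return out
    groups = {
        key: box_cox(sub[variable].to_numpy(dtype=float), transform)
        for key, sub in records.groupby(grouping, observed=True, sort=True)
    }
    pairs = list(itertools.combinations(sorted(groups, key=str), 2))
    m = len(pairs)
    rows = []
    for ga, gb in pairs:
        t, p = sps.ttest_ind(groups[ga], groups[gb], equal_var=equal_var)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "t": float(t),
                "p_raw": float(p),
                "p_adjusted": min(float(p) * m, 1.0),
                "n_comparisons": m,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["run"] = True
    return out


def ks_between_passages(
    records: pd.DataFrame,
    variable: str,
    reference_passage: str,
    passage_col: str = "passage",
) -> pd.DataFrame:
    """Two-sample KS tests of the reference passage against each other one.

    The KS statistic depends only on ranks, so any strictly increasing
    transform of both samples (e.g. log) gives identical D and p.
    """
    ref = records.loc[records[passage_col] == reference_passage, variable].to_numpy()
    if ref.size < 2:
        raise ValueError(f"reference passage {reference_passage!r} has n < 2")
    rows = []
    for passage, sub in records.groupby(passage_col, observed=True, sort=True):
        if passage == reference_passage:
            continue
        x = sub[variable].to_numpy()
        if x.size < 2:
            raise ValueError(f"passage {passage!r} has n < 2")
        res = sps.ks_2samp(ref, x)
        rows.append(
            {
                "reference": reference_passage,
                "passage": passage,
                "D": float(res.statistic),
                "p_value": float(res.pvalue),
                "n_ref": ref.size,
                "n": x.size,
            }
        )
    return pd.DataFrame(rows)


def fold_change_table(group_means: dict | pd.Series, reference: str) -> pd.DataFrame:
    """Fold change of each group mean against the reference group.

    The raw ratio is retained alongside the one-decimal rounded value
    used for reporting.
    """
    means = pd.Series(group_means, dtype=float)
    if reference not in means.index:
        raise KeyError(f"reference group {reference!r} not present")
    ref = means[reference]
    if ref == 0:
        raise ValueError("reference mean is zero")
    out = pd.DataFrame(
        {
            "group": means.index,
            "mean": means.to_numpy(),
            "fold_change_raw": (means / ref).to_numpy(),
        }
    )
    out["fold_change"] = out["fold_change_raw"].round(1)
    return out
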