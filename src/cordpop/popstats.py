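"""Population-level statistics linking morphology to impact biomechanics.

Pearson correlation matrix over morphology and outcome columns, peak-force
distribution summaries (5-N binning, moments, coefficient of variation,
Shapiro-Wilk normality), mean +/- k*SD outlier identification, and the
two-group comparison of mediolateral occlusion between subjects whose
white-matter lesion does / does not extend to the ipsilateral edge.

Only raw Pearson coefficients are reported (no multiple-testing
correction), matching how the correlation structure is conventionally
summarized for this analysis; sample statistics use the n-1 denominator
(the n-denominator variants are also reported where relevant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix", "ForceDistribution", "ExtensionGroupTest",
    "DEFAULT_CORRELATION_VARIABLES",
    "correlation_matrix", "force_distribution", "outliers",
    "extension_group_test",
]

#: Canonical column order of the morphology-biomechanics correlation matrix.
DEFAULT_CORRELATION_VARIABLES = [
    "SCOW", "SCOD", "SCW", "SCD", "SCO", "SC", "CSF_Area", "CSF_ML",
    "CSF_AP", "Occ_Area", "Occ_ML", "Occ_AP", "PeakForce_N", "Impulse_Ns",
    "GM_Sparing_pct", "WM_Sparing_pct",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson r matrix with per-pair sample sizes."""

    variables: list[str]
    r: pd.DataFrame
    n: pd.DataFrame

    def get(self, a: str, b: str) -> float:
        return float(self.r.loc[a, b])


@dataclass(frozen=True)
class ForceDistribution:
    """Histogram and summary of the population peak forces (N)."""

    bin_edges: np.ndarray       # half-open [k*w, (k+1)*w)
    counts: np.ndarray
    mean: float
    sd: float                   # n-1 denominator
    sd_n: float                 # n denominator
    minimum: float
    maximum: float
    cov_pct: float              # 100 * sd / mean
    shapiro_stat: float
    shapiro_p: float
    n: int


@dataclass(frozen=True)
class ExtensionGroupTest:
    """Welch two-sample comparison of Occ_ML by lateral-extension group.

    The underlying published comparison is labeled a paired t-test, but the
    two groups are independent subject sets of unequal size; it is
    implemented here as Welch's independent-samples test and flagged as
    such in ``note``.
    """

    t: float
    df: float
    p: float
    mean_extension: float
    mean_no_extension: float
    n_extension: int
    n_no_extension: int
    note: str = ("implemented as Welch's independent-samples t-test; the "
                 "groups are independent, not paired")

    @property
    def extension_group_higher(self) -> bool:
        return self.mean_extension > self.mean_no_extension


def correlation_matrix(table: pd.DataFrame,
                       variables: list[str] | None = None,
                       ) -> CorrelationMatrix:
    """Pairwise Pearson correlations over ``variables``.

    Pairwise deletion of missing values; a zero-variance column yields NaN
    (undefined, never coerced to 0).  Requires >= 3 complete rows per pair.
    """
    if variables is None:
        variables = [v for v in DEFAULT_CORRELATION_VARIABLES
                     if v in table.columns]
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    sub = table[variables].astype(float)
    notna = sub.notna()
    n = pd.DataFrame(notna.T.astype(int) @ notna.astype(int),
                     index=variables, columns=variables)
    if (n.values[np.triu_indices(len(variables), 1)] < 3).any():
        raise ValueError("need >= 3 complete rows for every variable pair")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = sub.corr(method="pearson", min_periods=3)
    np.fill_diagonal(r.values, 1.0)
    zero_var = sub.std(ddof=1) == 0
    r.loc[zero_var, :] = np.nan
    r.loc[:, zero_var] = np.nan
    return CorrelationMatrix(variables=list(variables), r=r, n=n)


def force_distribution(table: pd.DataFrame, bin_width_N: float = 5.0,
                       column: str = "PeakForce_N") -> ForceDistribution:
    """Bin peak forces in ``bin_width_N`` increments and summarize.

    Bins are half-open [k*w, (k+1)*w) anchored at 0.  Normality is
    assessed descriptively with Shapiro-Wilk (statistic and p reported,
    not thresholded).
    """
    f = np.asarray(table[column].dropna(), dtype=float)
    if f.size < 3:
        raise ValueError("need >= 3 peak-force values")
    k = np.floor(f / bin_width_N).astype(int)   # half-open [k*w, (k+1)*w)
    counts = np.bincount(k - k.min())
    edges = (np.arange(k.min(), k.max() + 2)) * bin_width_N
    sd = float(f.std(ddof=1))
    mean = float(f.mean())
    if f.std() == 0:
        shapiro_stat, shapiro_p = float("nan"), float("nan")
    else:
        shapiro_stat, shapiro_p = (float(v) for v in stats.shapiro(f))
    return ForceDistribution(
        bin_edges=edges, counts=counts, mean=mean, sd=sd,
        sd_n=float(f.std(ddof=0)), minimum=float(f.min()),
        maximum=float(f.max()),
        cov_pct=float(100.0 * sd / mean) if mean != 0 else float("nan"),
        shapiro_stat=shapiro_stat, shapiro_p=shapiro_p, n=int(f.size))


def outliers(table: pd.DataFrame, column: str = "PeakForce_N",
             k_sd: float = 2.0) -> list[str]:
    """Subject ids whose ``column`` value lies beyond mean +/- k_sd * SD."""
    vals = table[column].astype(float)
    mean, sd = vals.mean(), vals.std(ddof=1)
    mask = (vals - mean).abs() > k_sd * sd
    return list(table.loc[mask, "SubjectID"].astype(str))


def extension_group_test(table: pd.DataFrame,
                         value_column: str = "Occ_ML",
                         group_column: str = "LateralExtension",
                         ) -> ExtensionGroupTest:
    """Welch t-test of ``value_column`` between lateral-extension groups.

    Raises if either group has fewer than 2 members.
    """
    groups = table[group_column].astype(bool)
    a = table.loc[groups, value_column].astype(float).to_numpy()
    b = table.loc[~groups, value_column].astype(float).to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"each lateral-extension group needs >= 2 subjects "
            f"(got {a.size} with, {b.size} without)")
    res = stats.ttest_ind(a, b, equal_var=False)
    return ExtensionGroupTest(
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
        mean_extension=float(a.mean()), mean_no_extension=float(b.mean()),
        n_extension=int(a.size), n_no_extension=int(b.size))
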