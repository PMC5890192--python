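"""Sample-size-weighted merging of per-subject correlations and tests.

Subjects contribute a Pearson correlation r_i over n_i sentences between
reactivation intensity and understanding rating.  Because n_i varies
across subjects, the correlations are merged with the fixed-effect
meta-analytic scheme for Fisher-transformed correlations:

    Z_i = arctanh(r_i),  w_i = (n_i - 3) / sum_j (n_j - 3)
    zeta = sum_i w_i Z_i,    SE_zeta = 1 / sqrt(sum_i (n_i - 3))
    r_merged = tanh(zeta)

zeta / SE_zeta is standard normal under the null r_merged = 0, and
(zeta_1 - zeta_2) / sqrt(SE_1^2 + SE_2^2) compares two independent merged
correlations.  An above/below-average split with a paired t-test across
subjects and Bonferroni correction round out the machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .rsa import fisher_z, inverse_fisher

__all__ = [
    "SubjectCorrelation",
    "MergedCorrelation",
    "SplitResult",
    "per_subject_correlation",
    "FisherZMergedCorrelation",
    "merge_correlations",
    "test_merged_zero",
    "compare_merged",
    "above_below_split",
    "bonferroni",
]


@dataclass(frozen=True)
class SubjectCorrelation:
    """One subject's intensity-rating correlation and its sample size."""

    subject_id: object
    r: float
    n: int
    condition: str = ""

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"correlation out of range: {self.r}")
        if self.n < 4:
            raise ValueError("n must be at least 4 (weights need n - 3 > 0)")


@dataclass(frozen=True)
class MergedCorrelation:
    """Weighted Fisher-Z merged correlation with its standard error."""

    zeta: float
    se: float
    r_merged: float
    z_stat: float
    p_value: float
    sidedness: str
    n_subjects: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if abs(self.r_merged - np.tanh(self.zeta)) > 1e-9:
            raise ValueError("r_merged inconsistent with zeta")


def _normal_p(z: float, sidedness: str) -> float:
    if sidedness == "one":
        return float(sps.norm.sf(z))
    if sidedness == "two":
        return float(2.0 * sps.norm.sf(abs(z)))
    raise ValueError("sidedness must be 'one' or 'two'")


def per_subject_correlation(
    intensities: pd.DataFrame,
    ratings: pd.DataFrame,
    condition: str = "",
    min_n: int = 4,
) -> list[SubjectCorrelation]:
    """Pearson r per subject between matched intensities and ratings.

    Both tables need ``subject`` and ``sentence_id`` columns plus an
    ``intensity`` / ``rating`` column; rows are matched on (subject,
    sentence).  Subjects with fewer than ``min_n`` matched sentences or
    with zero variance on either variable are dropped with a warning.
    """
    merged = intensities.merge(ratings, on=["subject", "sentence_id"])
    out = []
    for sub, grp in merged.groupby("subject", sort=True):
        x = grp["intensity"].to_numpy(dtype=float)
        y = grp["rating"].to_numpy(dtype=float)
        if x.size < min_n:
            warnings.warn(f"subject {sub!r}: only {x.size} sentences, dropped")
            continue
        if x.std() == 0 or y.std() == 0:
            warnings.warn(f"subject {sub!r}: zero variance, dropped")
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        out.append(SubjectCorrelation(subject_id=sub, r=r, n=x.size, condition=condition))
    return out


class FisherZMergedCorrelation(BaseEstimator):
    """Fixed-effect merge of per-subject correlations in Fisher-Z space.

    Parameters
    ----------
    sidedness : {'one', 'two'}, default 'one'
        Direction of the null-hypothesis test stored in ``p_value_``; the
        one-sided version tests for a positive merged correlation.

    Attributes (after ``fit(r, n)``)
    --------------------------------
    zeta_, se_, r_merged_, z_, p_value_, weights_
    """

    def __init__(self, sidedness: str = "one"):
        self.sidedness = sidedness

    def fit(self, r: Sequence[float], n: Sequence[int]):
        r = np.asarray(r, dtype=float).ravel()
        n = np.asarray(n, dtype=float).ravel()
        if r.size == 0 or r.size != n.size:
            raise ValueError("r and n must be equal-length and non-empty")
        if (np.abs(r) > 1).any():
            raise ValueError("correlations must lie in [-1, 1]")
        if (n <= 3).any():
            raise ValueError("every subject needs n > 3")
        Z = fisher_z(r)
        dof = n - 3.0
        self.weights_ = dof / dof.sum()
        self.zeta_ = float(self.weights_ @ Z)
        self.se_ = float(1.0 / np.sqrt(dof.sum()))
        self.r_merged_ = float(inverse_fisher(self.zeta_))
        self.z_ = self.zeta_ / self.se_
        self.p_value_ = _normal_p(self.z_, self.sidedness)
        return self

    def merged_(self) -> MergedCorrelation:
        return MergedCorrelation(
            zeta=self.zeta_,
            se=self.se_,
            r_merged=self.r_merged_,
            z_stat=self.z_,
            p_value=self.p_value_,
            sidedness=self.sidedness,
            n_subjects=int(self.weights_.size),
        )


def merge_correlations(
    subs: Sequence[SubjectCorrelation], sidedness: str = "one"
) -> MergedCorrelation:
    """Weighted Fisher-Z merge of a list of subject correlations."""
    if not subs:
        raise ValueError("no subject correlations to merge")
    est = FisherZMergedCorrelation(sidedness=sidedness).fit(
        [s.r for s in subs], [s.n for s in subs]
    )
    return est.merged_()


def test_merged_zero(m: MergedCorrelation, sidedness: str = "one") -> float:
    """p-value for the null zeta = 0 (i.e. r_merged = 0)."""
    return _normal_p(m.zeta / m.se, sidedness)


test_merged_zero.__test__ = False  # library API, not a pytest case


def compare_merged(
    m1: MergedCorrelation, m2: MergedCorrelation, sidedness: str = "two"
) -> tuple[float, float]:
    """z and p for the difference of two independent merged correlations."""
    z = (m1.zeta - m2.zeta) / np.sqrt(m1.se**2 + m2.se**2)
    return float(z), _normal_p(float(z), sidedness)


@dataclass(frozen=True)
class SplitResult:
    """Above/below-average intensity split, paired across subjects."""

    per_subject: pd.DataFrame  # subject, mean_above, mean_below
    t_stat: float
    p_value: float
    dof: int
    sidedness: str


def above_below_split(
    intensities: pd.DataFrame,
    ratings: pd.DataFrame,
    sidedness: str = "one",
) -> SplitResult:
    """Mean rating of above- vs below-average-intensity sentences.

    Within each subject, sentences are split at the subject's own mean
    intensity; the two mean ratings are compared across subjects with a
    paired t-test (one-sided tests the facilitation direction, above >
    below).  Subjects with an empty side (e.g. all intensities equal) are
    dropped with a warning.
    """
    merged = intensities.merge(ratings, on=["subject", "sentence_id"])
    rows = []
    for sub, grp in merged.groupby("subject", sort=True):
        x = grp["intensity"].to_numpy(dtype=float)
        y = grp["rating"].to_numpy(dtype=float)
        above = x > x.mean()
        below = x < x.mean()
        if not above.any() or not below.any():
            warnings.warn(f"subject {sub!r}: empty split side, dropped")
            continue
        rows.append(
            {"subject": sub, "mean_above": y[above].mean(), "mean_below": y[below].mean()}
        )
    per_subject = pd.DataFrame(rows)
    if len(per_subject) < 2:
        raise ValueError("need at least 2 subjects with both split sides")
    res = sps.ttest_rel(
        per_subject["mean_above"],
        per_subject["mean_below"],
        alternative="greater" if sidedness == "one" else "two-sided",
    )
    return SplitResult(
        per_subject=per_subject,
        t_stat=float(res.statistic),
        p_value=float(res.pvalue),
        dof=len(per_subject) - 1,
        sidedness=sidedness,
    )


def bonferroni(p_values, m: int | None = None):
    """Bonferroni correction: p_corrected = min(1, m * p).

    ``m`` defaults to the number of p-values but may be larger (a family
    wider than the values passed in).
    """
    p = np.asarray(p_values, dtype=float)
    m_eff = p.size if m is None else int(m)
    if m_eff < p.size:
        raise ValueError("m must be at least the number of tests")
    out = np.minimum(1.0, m_eff * p)
    return float(out) if np.isscalar(p_values) or p.ndim == 0 else out
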