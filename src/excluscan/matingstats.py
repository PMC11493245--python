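"""Transfer frequencies, exclusion indices and group-mean statistics.

A mating assay counts donor, recipient and transconjugant CFUs per
replicate. The transfer frequency is ``T = transconjugants / donors``; the
exclusion index of a recipient is ``EI = T_empty / T_test``, the fold by
which a plasmid-bearing (or exclusion-factor-expressing) recipient reduces
incoming transfer relative to a plasmid-free one. EI ≈ 1 means no exclusion.

Transfer frequencies span many orders of magnitude and are treated as
log-normal: group comparisons run on log10-transformed values — Bartlett's
test for homogeneity of variance, one-way ANOVA, a Tukey-Kramer post-hoc
test (studentized-range p-values, Kramer adjustment for unequal group
sizes), and a compact letter display in which groups sharing a letter are
not statistically different.

Replicates with zero transconjugants are censored at the detection limit
``1 / donor_cfu`` (one colony on the undiluted plate) so they survive the
log transform; derived exclusion indices inherit a lower-bound flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MatingRecord",
    "TransferFrequency",
    "ExclusionIndex",
    "GroupComparison",
    "transfer_frequency",
    "transfer_frequencies",
    "exclusion_index",
    "bartlett_test",
    "anova_oneway",
    "tukey_kramer",
    "compact_letter_display",
    "compare_groups",
]


@dataclass(frozen=True)
class MatingRecord:
    donor_label: str
    recipient_label: str
    donor_cfu: float
    recipient_cfu: float
    transconjugant_cfu: float
    replicate: int = 1

    def __post_init__(self):
        if min(self.donor_cfu, self.recipient_cfu, self.transconjugant_cfu) < 0:
            raise ValueError("CFU counts must be non-negative")


@dataclass(frozen=True)
class TransferFrequency:
    value: float
    censored: bool = False

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("transfer frequency must be >= 0")


@dataclass(frozen=True)
class ExclusionIndex:
    value: float
    lower_bound: bool = False

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("exclusion index must be > 0")


@dataclass
class GroupComparison:
    labels: list
    means: np.ndarray          # group means of log10 T
    variances: np.ndarray      # group variances (ddof=1) of log10 T
    bartlett_stat: float
    bartlett_p: float
    anova_f: float
    anova_df: tuple
    anova_p: float
    tukey_p: pd.DataFrame      # symmetric pairwise p matrix
    letters: dict              # label -> letter string


def transfer_frequency(rec: MatingRecord) -> TransferFrequency:
    """T = transconjugant CFUs / donor CFUs.

    Zero transconjugants are censored at the detection limit 1/donor_cfu so
    that downstream log-scale analyses keep the replicate.
    """
    if rec.donor_cfu <= 0:
        raise ValueError("transfer frequency undefined for donor_cfu = 0")
    if rec.transconjugant_cfu == 0:
        return TransferFrequency(value=1.0 / rec.donor_cfu, censored=True)
    return TransferFrequency(value=rec.transconjugant_cfu / rec.donor_cfu)


def transfer_frequencies(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`transfer_frequency` over a mating CFU table.

    Adds ``frequency`` and ``censored`` columns.
    """
    if (df["donor_cfu"] <= 0).any():
        raise ValueError("transfer frequency undefined for donor_cfu = 0")
    out = df.copy()
    censored = out["transconjugant_cfu"] == 0
    tc = out["transconjugant_cfu"].where(~censored, 1.0)
    out["frequency"] = tc / out["donor_cfu"]
    out["censored"] = censored
    return out


def exclusion_index(
    freq_empty: TransferFrequency, freq_test: TransferFrequency
) -> ExclusionIndex:
    """EI = T_empty / T_test; a censored test frequency makes EI a lower bound."""
    if freq_empty.value <= 0 or freq_test.value <= 0:
        raise ValueError("exclusion index undefined for zero frequencies")
    return ExclusionIndex(
        value=freq_empty.value / freq_test.value, lower_bound=freq_test.censored
    )


def _check_groups(groups) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    return arrs


def bartlett_test(groups) -> tuple[float, float]:
    """Bartlett's chi-square test of equal variances across groups.

    Returns ``(statistic, p)``; the p-value uses the chi-square distribution
    with k-1 df. All-identical data (every group variance zero) gives
    statistic 0, p 1.
    """
    arrs = _check_groups(groups)
    if any(len(a) < 2 for a in arrs):
        raise ValueError("each group needs at least two values")
    if all(np.var(a, ddof=1) == 0 for a in arrs):
        return 0.0, 1.0
    stat, p = stats.bartlett(*arrs)
    return float(stat), float(p)


def anova_oneway(groups) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA on the supplied groups.

    Returns ``(F, df_between, df_within, p)`` from the between/within
    sums-of-squares decomposition. Degenerate all-constant input (zero
    between- and within-group variance) gives F = 0, p = 1; distinct means
    with zero within-group variance give F = inf, p = 0.
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    n = sum(len(a) for a in arrs)
    if n <= k:
        raise ValueError("need more observations than groups")
    df1, df2 = k - 1, n - k
    grand = np.concatenate(arrs).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    if ssw == 0:
        if ssb == 0:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    f = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def tukey_kramer(groups, labels=None) -> pd.DataFrame:
    """Pairwise Tukey-Kramer p-values.

    For groups *i*, *j*: ``q = |m_i - m_j| / sqrt((MSW/2)(1/n_i + 1/n_j))``
    with MSW the ANOVA within-group mean square; p comes from the
    studentized-range distribution with k groups and within-group df
    (scipy's numerically integrated CDF). Returns a symmetric DataFrame
    with unit diagonal.
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    n = sum(len(a) for a in arrs)
    df2 = n - k
    if df2 <= 0:
        raise ValueError("need more observations than groups")
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrs) / df2
    means = [a.mean() for a in arrs]

    p = np.ones((k, k))
    for i, j in combinations(range(k), 2):
        diff = abs(means[i] - means[j])
        if msw == 0:
            pij = 1.0 if diff == 0 else 0.0
        else:
            q = diff / np.sqrt((msw / 2.0) * (1.0 / len(arrs[i]) + 1.0 / len(arrs[j])))
            pij = float(stats.studentized_range.sf(q, k, df2))
        p[i, j] = p[j, i] = pij
    return pd.DataFrame(p, index=labels, columns=labels)


def compact_letter_display(pmatrix: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Insert-and-absorb compact letter display.

    Two groups share at least one letter iff their pairwise p-value is
    >= ``alpha``. Starts from a single letter covering all groups; each
    significant pair splits every letter containing both members into two,
    then letters that are subsets of others are absorbed.
    """
    labels = list(pmatrix.index)
    p = pmatrix.to_numpy()
    if p.shape[0] != p.shape[1] or not np.allclose(p, p.T):
        raise ValueError("p matrix must be square and symmetric")
    k = len(labels)

    columns: list[set] = [set(range(k))]
    for i, j in combinations(range(k), 2):
        if p[i, j] >= alpha:
            continue
        new_columns = []
        for col in columns:
            if i in col and j in col:
                new_columns.extend([col - {i}, col - {j}])
            else:
                new_columns.append(col)
        # absorb columns contained in another
        columns = []
        for col in new_columns:
            if any(col < other or (col == other and other in columns) for other in new_columns):
                continue
            columns.append(col)

    def letter(idx: int) -> str:
        # a..z, then aa, ab, ... for pathological cases
        s = ""
        idx += 1
        while idx:
            idx, rem = divmod(idx - 1, 26)
            s = chr(ord("a") + rem) + s
        return s

    out = {lab: "" for lab in labels}
    for ci, col in enumerate(columns):
        for g in sorted(col):
            out[labels[g]] += letter(ci)
    return out


def compare_groups(groups, labels=None, alpha: float = 0.05, log10: bool = True) -> GroupComparison:
    """Full group-mean analysis of transfer frequencies.

    Applies the log10 transform (unless ``log10=False``), then Bartlett,
    one-way ANOVA, Tukey-Kramer and the compact letter display.
    """
    arrs = _check_groups(groups)
    if log10:
        if any((a <= 0).any() for a in arrs):
            raise ValueError("log10 transform requires positive frequencies")
        arrs = [np.log10(a) for a in arrs]
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrs))]

    b_stat, b_p = bartlett_test(arrs)
    f, df1, df2, p = anova_oneway(arrs)
    tk = tukey_kramer(arrs, labels=labels)
    letters = compact_letter_display(tk, alpha=alpha)
    return GroupComparison(
        labels=list(labels),
        means=np.array([a.mean() for a in arrs]),
        variances=np.array([a.var(ddof=1) for a in arrs]),
        bartlett_stat=b_stat,
        bartlett_p=b_p,
        anova_f=f,
        anova_df=(df1, df2),
        anova_p=p,
        tukey_p=tk,
        letters=letters,
    )
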