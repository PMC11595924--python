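"""Duncan's new multiple range test (DMRT) with compact letter display.

Given k level means with a pooled error mean square, DMRT compares the
ordered means stepwise. For a stretch spanning p ordered means the least
significant range is

    LSR_p = q(p, nu, 1 - gamma_p) * sqrt(MSE / n),

where q is the studentized-range quantile and gamma_p = 1 - (1-alpha)^(p-1)
is Duncan's span-dependent protection level. The protected rule: a pair of
means is declared non-significant when any window of the ordered means that
contains both has a range below its own LSR. Means are labelled so that two
levels share a letter iff they are not significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import studentized_range

from .traits import ValidationError

__all__ = ["DuncanResult", "studentized_range_quantile", "duncan_letters"]


@lru_cache(maxsize=4096)
def _srq_cached(k_span: int, df: int, prob: float) -> float:
    return float(studentized_range.ppf(prob, k_span, df))


def studentized_range_quantile(k_span: int, df: int, prob: float) -> float:
    """Quantile of the studentized range of ``k_span`` means with ``df``
    error degrees of freedom: the value q with CDF(q) = ``prob``.

    Monotone increasing in ``k_span`` and ``prob``, decreasing in ``df``.
    Cached — the underlying numerical inversion is expensive.
    """
    if k_span < 2:
        raise ValueError("k_span must be >= 2")
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must lie in (0, 1)")
    return _srq_cached(int(k_span), int(df), float(prob))


@dataclass
class DuncanResult:
    """Sorted means, least significant ranges and letter groups."""

    alpha: float
    error_df: int
    mse: float
    n_per_mean: float
    sorted_levels: list  # descending by mean; ties by level id
    sorted_means: list[float]
    lsr: dict[int, float]  # span p -> least significant range
    letters: dict  # level -> letter string
    degenerate: bool = False

    def nonsignificant(self, level_a, level_b) -> bool:
        """Whether the two levels share at least one letter."""
        return bool(set(self.letters[level_a]) & set(self.letters[level_b]))


def _letter_string(index: int) -> str:
    """0 -> 'a', 25 -> 'z', 26 -> 'aa', ... (excel-column style)."""
    out = ""
    index += 1
    while index:
        index, rem = divmod(index - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def _letters_from_stretches(
    levels: Sequence, stretches: list[tuple[int, int]]
) -> dict:
    """Assign letters to maximal non-significant stretches of the ordered
    means; uncovered singletons get their own letter."""
    k = len(levels)
    # maximal stretches only
    maximal = [
        (i, j)
        for (i, j) in stretches
        if not any(
            (a <= i and j <= b) and (a, b) != (i, j) for (a, b) in stretches
        )
    ]
    covered = set()
    for i, j in maximal:
        covered.update(range(i, j + 1))
    groups = sorted(
        maximal + [(i, i) for i in range(k) if i not in covered]
    )
    letters: dict = {lv: "" for lv in levels}
    for g, (i, j) in enumerate(groups):
        s = _letter_string(g)
        for idx in range(i, j + 1):
            letters[levels[idx]] += s
    return letters


def duncan_letters(
    means: Mapping,
    n_per_mean: float | Mapping,
    mse: float,
    error_df: int,
    alpha: float = 0.01,
) -> DuncanResult:
    """Duncan's protected stepwise comparison of level means.

    Parameters
    ----------
    means
        level -> mean. Levels are sorted descending by mean, ties broken by
        the level identifier (stable; ties never split a letter group).
    n_per_mean
        Replicates behind each mean; a mapping of unequal sizes is reduced
        to its harmonic mean (standard DMRT practice for mild imbalance).
    mse, error_df
        Pooled error mean square and its degrees of freedom.
    alpha
        Per-comparison significance level of the letter display.
    """
    if len(means) < 2:
        raise ValidationError("duncan_letters needs >= 2 levels")
    if error_df < 1:
        raise ValidationError("error_df must be >= 1")
    if mse < 0:
        raise ValidationError("mse must be non-negative")
    if isinstance(n_per_mean, Mapping):
        sizes = np.array([float(v) for v in n_per_mean.values()])
        if (sizes <= 0).any():
            raise ValidationError("group sizes must be positive")
        n_eff = len(sizes) / (1.0 / sizes).sum()
    else:
        n_eff = float(n_per_mean)
        if n_eff <= 0:
            raise ValidationError("n_per_mean must be positive")

    order = sorted(means, key=lambda lv: (-means[lv], str(lv)))
    sorted_means = [float(means[lv]) for lv in order]
    k = len(order)

    if mse == 0.0:
        # degenerate: no error variance — distinct means are distinct groups
        stretches = []
        i = 0
        while i < k:
            j = i
            while j + 1 < k and sorted_means[j + 1] == sorted_means[i]:
                j += 1
            if j > i:
                stretches.append((i, j))
            i = j + 1
        letters = _letters_from_stretches(order, stretches)
        return DuncanResult(
            alpha=alpha,
            error_df=error_df,
            mse=0.0,
            n_per_mean=n_eff,
            sorted_levels=order,
            sorted_means=sorted_means,
            lsr={},
            letters=letters,
            degenerate=True,
        )

    se = float(np.sqrt(mse / n_eff))
    lsr: dict[int, float] = {}
    for p in range(2, k + 1):
        gamma_p = 1.0 - (1.0 - alpha) ** (p - 1)
        lsr[p] = studentized_range_quantile(p, error_df, 1.0 - gamma_p) * se

    # Protected stepwise sweep, largest spans first: a window whose range
    # falls below its LSR (or that sits inside such a window) is a
    # non-significant stretch; its sub-pairs are never re-tested.
    stretches: list[tuple[int, int]] = []
    for p in range(k, 1, -1):
        for i in range(0, k - p + 1):
            j = i + p - 1
            if any(a <= i and j <= b for (a, b) in stretches):
                continue
            if sorted_means[i] - sorted_means[j] < lsr[p]:
                stretches.append((i, j))

    letters = _letters_from_stretches(order, stretches)
    return DuncanResult(
        alpha=alpha,
        error_df=error_df,
        mse=float(mse),
        n_per_mean=n_eff,
        sorted_levels=order,
        sorted_means=sorted_means,
        lsr=lsr,
        letters=letters,
        degenerate=False,
    )
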