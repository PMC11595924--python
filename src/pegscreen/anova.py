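"""Fixed-effects ANOVA for the screening design.

Two layouts are supported: a one-way completely randomised design (CRD,
accession or tolerance class as the single factor) and the balanced
two-way accession x PEG-concentration factorial with replicates. Sums of
squares are the standard balanced-design decompositions; each effect is
tested against the pooled error mean square with an upper-tail F p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .traits import StudyTable, ValidationError

__all__ = ["AnovaRow", "AnovaTable", "one_way_anova", "two_way_anova"]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float
    F: float  # nan where no test applies (error/total rows)
    p: float  # nan where no test applies


@dataclass
class AnovaTable:
    """Source/df/SS/MS/F/p decomposition.

    ``degenerate`` flags a zero error mean square (F reported as +inf with
    p = 0, or nan when the between-SS also vanishes).
    """

    rows: list[AnovaRow]
    degenerate: bool = False

    def row(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    @property
    def sources(self) -> list[str]:
        return [r.source for r in self.rows]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "source": r.source,
                    "df": r.df,
                    "SS": r.ss,
                    "MS": r.ms,
                    "F": r.F,
                    "p": r.p,
                }
                for r in self.rows
            ]
        )

    def _check(self) -> None:
        total = self.row("total")
        parts = [r for r in self.rows if r.source != "total"]
        if sum(r.df for r in parts) != total.df:
            raise AssertionError("ANOVA df do not sum to total df")
        ss_sum = sum(r.ss for r in parts)
        scale = max(abs(total.ss), 1.0)
        if abs(ss_sum - total.ss) > 1e-6 * scale:
            raise AssertionError("ANOVA SS do not sum to total SS")


def _f_test(ss_effect: float, df_effect: int, ms_error: float, df_error: int):
    """F ratio and upper-tail p against the error mean square.

    A zero error MS is the degenerate case: F = +inf (p = 0) when the
    effect SS is positive, nan when it vanishes too.
    """
    ms = ss_effect / df_effect if df_effect > 0 else np.nan
    if df_effect <= 0:
        return np.nan, np.nan, np.nan, False
    if ms_error <= 0:
        if ss_effect > 0:
            return ms, np.inf, 0.0, True
        return ms, np.nan, np.nan, True
    f = ms / ms_error
    p = float(stats.f.sf(f, df_effect, df_error))
    return ms, float(f), p, False


def one_way_anova(groups: list[np.ndarray], factor: str = "between") -> AnovaTable:
    """One-way CRD ANOVA from a list of per-group replicate samples.

    Requires >= 2 groups with >= 2 values each. Returns rows
    ``factor``/``error``/``total``.
    """
    if len(groups) < 2:
        raise ValidationError("one-way ANOVA needs at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValidationError("every group needs at least 2 values")
    all_vals = np.concatenate(groups)
    n = all_vals.size
    k = len(groups)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_total = ((all_vals - grand) ** 2).sum()
    df_b, df_w = k - 1, n - k
    ms_w = ss_within / df_w
    ms_b, f, p, degen = _f_test(ss_between, df_b, ms_w, df_w)
    table = AnovaTable(
        rows=[
            AnovaRow(factor, df_b, float(ss_between), float(ms_b), f, p),
            AnovaRow("error", df_w, float(ss_within), float(ms_w), np.nan, np.nan),
            AnovaRow("total", n - 1, float(ss_total), np.nan, np.nan, np.nan),
        ],
        degenerate=degen,
    )
    table._check()
    return table


def two_way_anova(table: StudyTable, trait: str) -> AnovaTable:
    """Balanced two-way factorial ANOVA of one trait:
    accession x PEG concentration with r replicates per cell.

    Every (accession, treatment) cell must hold the same replicate count
    r >= 2; unbalanced designs are rejected (subset or rebalance first).
    Rows: ``accession``, ``peg``, ``accession:peg``, ``error``, ``total``.
    """
    sub = table.data[table.data["trait"] == trait]
    if sub.empty:
        raise ValidationError(f"no observations for trait {trait!r}")
    counts = sub.groupby(["accession", "treatment"])["value"].count()
    accessions = sorted(sub["accession"].unique())
    treatments = sorted(sub["treatment"].unique())
    if len(accessions) < 2:
        raise ValidationError("two-way ANOVA needs >= 2 accessions")
    if len(counts) != len(accessions) * len(treatments) or counts.nunique() != 1:
        raise ValidationError(
            "unbalanced design: every (accession, treatment) cell must have "
            "the same replicate count; subset or rebalance the table"
        )
    r = int(counts.iloc[0])
    if r < 2:
        raise ValidationError("two-way ANOVA needs >= 2 replicates per cell")

    # a x b x r value array in sorted (accession, treatment, replicate) order
    a, b = len(accessions), len(treatments)
    ordered = sub.sort_values(["accession", "treatment", "replicate"])
    y = ordered["value"].to_numpy().reshape(a, b, r)

    grand = y.mean()
    cell = y.mean(axis=2)          # a x b cell means
    m_a = cell.mean(axis=1)        # accession means
    m_b = cell.mean(axis=0)        # treatment means

    ss_a = r * b * ((m_a - grand) ** 2).sum()
    ss_b = r * a * ((m_b - grand) ** 2).sum()
    ss_ab = r * (
        (cell - m_a[:, None] - m_b[None, :] + grand) ** 2
    ).sum()
    ss_err = ((y - cell[:, :, None]) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()

    df_a, df_b_ = a - 1, b - 1
    df_ab = df_a * df_b_
    df_err = a * b * (r - 1)
    ms_err = ss_err / df_err

    rows = []
    degenerate = False
    for source, ss, df in (
        ("accession", ss_a, df_a),
        ("peg", ss_b, df_b_),
        ("accession:peg", ss_ab, df_ab),
    ):
        if df == 0:  # single treatment level: effect not estimable
            rows.append(AnovaRow(source, 0, 0.0, np.nan, np.nan, np.nan))
            continue
        ms, f, p, degen = _f_test(ss, df, ms_err, df_err)
        degenerate = degenerate or degen
        rows.append(AnovaRow(source, df, float(ss), float(ms), f, p))
    rows.append(
        AnovaRow("error", df_err, float(ss_err), float(ms_err), np.nan, np.nan)
    )
    rows.append(
        AnovaRow("total", a * b * r - 1, float(ss_tot), np.nan, np.nan, np.nan)
    )
    out = AnovaTable(rows=rows, degenerate=degenerate)
    out._check()
    return out
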