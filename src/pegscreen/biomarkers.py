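"""Tolerance-group trait comparison and biomarker identification.

After accessions are classed as high / moderate / low tolerance, each
biochemical trait is compared across the classes under each stress
treatment: a one-way ANOVA over the class groups (on accession means, so
the spread reflects between-accession variation) plus a Duncan letter
display on the class means. Traits significant under *every* stress
treatment are the biomarker set — the traits whose accumulation separates
tolerant from susceptible material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anova import one_way_anova
from .dmrt import duncan_letters
from .ranking import ToleranceClasses
from .traits import BIOCHEMICAL, StudyTable, ValidationError, parse_treatment

__all__ = ["GroupStat", "BiomarkerReport", "group_trait_stats", "identify_biomarkers"]

STRESS_TREATMENTS = ("T1", "T2")


@dataclass(frozen=True)
class GroupStat:
    """Mean +/- SD of one tolerance class for one trait x treatment."""

    trait: str
    treatment: str
    klass: str
    n: int
    mean: float
    sd: float
    letter: str


def _class_values(
    table: StudyTable, classes: ToleranceClasses, trait: str, treatment: str
) -> dict[str, pd.Series]:
    code = parse_treatment(treatment).code
    sub = table.data[
        (table.data["trait"] == trait) & (table.data["treatment"] == code)
    ]
    if sub.empty:
        raise ValidationError(f"no {trait} observations under {code}")
    acc_means = sub.groupby("accession")["value"].mean()
    out: dict[str, pd.Series] = {}
    for label in sorted(set(classes.classes.values())):
        members = [a for a in classes.members(label) if a in acc_means.index]
        if len(members) < 2:
            raise ValidationError(
                f"class {label!r} has fewer than 2 accessions with "
                f"{trait} data under {code}"
            )
        out[label] = acc_means.loc[members]
    if len(out) < 2:
        raise ValidationError("need at least 2 tolerance classes")
    return out


def group_trait_stats(
    table: StudyTable,
    classes: ToleranceClasses,
    trait: str,
    treatment: str,
    alpha: float = 0.01,
) -> tuple[list[GroupStat], float]:
    """Class-wise mean/SD with Duncan letters, plus the across-class
    ANOVA p-value, for one trait under one stress treatment."""
    groups = _class_values(table, classes, trait, treatment)
    labels = list(groups)
    anova = one_way_anova([groups[g].to_numpy() for g in labels], factor="class")
    p = anova.row("class").p
    mse = anova.row("error").ms
    err_df = anova.row("error").df
    means = {g: float(groups[g].mean()) for g in labels}
    sizes = {g: float(len(groups[g])) for g in labels}
    letters = duncan_letters(
        means, sizes, mse=mse, error_df=err_df, alpha=alpha
    ).letters
    code = parse_treatment(treatment).code
    stats = [
        GroupStat(
            trait=trait,
            treatment=code,
            klass=g,
            n=int(sizes[g]),
            mean=means[g],
            sd=float(groups[g].std(ddof=1)),
            letter=letters[g],
        )
        for g in labels
    ]
    return stats, float(p)


@dataclass
class BiomarkerReport:
    """Per (trait, treatment) significance and the discriminating traits.

    ``biomarkers`` holds the traits with p <= alpha under every stress
    treatment, ordered by worst-case p (most conclusive first).
    """

    alpha: float
    treatments: tuple[str, ...]
    p_values: dict[tuple[str, str], float]  # (trait, treatment) -> p
    group_stats: list[GroupStat]
    biomarkers: list[str]

    def is_significant(self, trait: str, treatment: str) -> bool:
        return self.p_values[(trait, treatment)] <= self.alpha

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (trait, treatment), p in sorted(self.p_values.items()):
            row = {
                "treatment": treatment,
                "trait": trait,
                "p_value": p,
                "significant": p <= self.alpha,
            }
            for gs in self.group_stats:
                if gs.trait == trait and gs.treatment == treatment:
                    row[f"{gs.klass}_mean"] = gs.mean
                    row[f"{gs.klass}_sd"] = gs.sd
                    row[f"{gs.klass}_letter"] = gs.letter
            rows.append(row)
        return pd.DataFrame(rows)


def identify_biomarkers(
    table: StudyTable,
    classes: ToleranceClasses,
    traits: tuple[str, ...] = BIOCHEMICAL,
    treatments: tuple[str, ...] = STRESS_TREATMENTS,
    alpha: float = 0.01,
) -> BiomarkerReport:
    """Run the class comparison for every trait x stress treatment and
    collect the traits significant under all of them."""
    if not traits:
        raise ValidationError("no traits to analyze")
    p_values: dict[tuple[str, str], float] = {}
    all_stats: list[GroupStat] = []
    for trait in traits:
        for treatment in treatments:
            stats, p = group_trait_stats(table, classes, trait, treatment, alpha)
            p_values[(trait, str(parse_treatment(treatment).code))] = p
            all_stats.extend(stats)
    worst: dict[str, float] = {
        t: max(p_values[(t, parse_treatment(tr).code)] for tr in treatments)
        for t in traits
    }
    biomarkers = sorted(
        (t for t in traits if worst[t] <= alpha), key=lambda t: (worst[t], t)
    )
    return BiomarkerReport(
        alpha=alpha,
        treatments=tuple(parse_treatment(t).code for t in treatments),
        p_values=p_values,
        group_stats=all_stats,
        biomarkers=biomarkers,
    )
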