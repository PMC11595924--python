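"""Stress-tolerance index, average-rank aggregation and tolerance classes.

The screening ranks accessions two ways and combines them:

* **STI** (Fernandez stress tolerance index) per trait component:
  ``STI = (Y_p * Y_s) / Ybar_p**2`` with ``Y_p`` the accession's control
  mean, ``Y_s`` its stress mean and ``Ybar_p`` the grand control mean.
  Accessions productive under both conditions score high; an average
  accession with no stress loss scores 1.
* **AR** (average rank): each trait ranks the accessions (1 = best under
  the trait's orientation, mid-ranks on ties); AR is the mean of the
  per-trait ranks over a configured trait set. Lower is better.

Per stress treatment (scope T1 or T2) accessions are ordered by STI
descending; for the combined scope (trait values averaged over T1 and T2
before ranking) they are ordered by AR ascending. The final ordering is
sliced into near-equal high / moderate / low tolerance classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .traits import (
    StudyTable,
    TRAIT_BY_NAME,
    TRAIT_NAMES,
    ValidationError,
    accession_means,
)

__all__ = [
    "RankingConfig",
    "RankTable",
    "ToleranceClasses",
    "compute_sti",
    "aggregate_sti",
    "combined_sti",
    "rank_by_trait",
    "average_rank",
    "build_rank_table",
    "classify",
]

SCOPES = ("T1", "T2", "combined")

#: default AR trait set: all 12 traits minus LP (a damage marker whose
#: ranks are already captured through its lower-is-better orientation but
#: which the 11-component average-rank convention excludes).
DEFAULT_RANKED_TRAITS: tuple[str, ...] = tuple(
    t for t in TRAIT_NAMES if t != "LP"
)

#: default STI basis: germination plus seedling growth (root + shoot
#: length, summed per replicate before averaging).
DEFAULT_STI_COMPONENTS: tuple[str, ...] = ("GP", "RL+SL")


@dataclass(frozen=True)
class RankingConfig:
    """Trait sets, orientations and ordering policies for the ranking."""

    ranked_traits: tuple[str, ...] = DEFAULT_RANKED_TRAITS
    sti_components: tuple[str, ...] = DEFAULT_STI_COMPONENTS
    orientation_overrides: Mapping[str, str] = field(default_factory=dict)
    # scope -> "sti_desc" | "ar_asc"
    final_order_policy: Mapping[str, str] = field(
        default_factory=lambda: {
            "T1": "sti_desc",
            "T2": "sti_desc",
            "combined": "ar_asc",
        }
    )

    def __post_init__(self) -> None:
        if not self.ranked_traits:
            raise ValidationError("ranked_traits must be non-empty")
        if not self.sti_components:
            raise ValidationError("sti_components must be non-empty")
        bad = [t for t in self.ranked_traits if t not in TRAIT_NAMES]
        if bad:
            raise ValidationError(f"unknown ranked trait(s): {bad}")
        for comp in self.sti_components:
            for t in comp.split("+"):
                if t not in TRAIT_NAMES:
                    raise ValidationError(
                        f"unknown trait {t!r} in STI component {comp!r}"
                    )
        for scope, policy in self.final_order_policy.items():
            if policy not in ("sti_desc", "ar_asc"):
                raise ValidationError(f"unknown order policy {policy!r}")

    def orientation(self, trait: str) -> str:
        if trait in self.orientation_overrides:
            return self.orientation_overrides[trait]
        return TRAIT_BY_NAME[trait].orientation


def compute_sti(
    y_control: float, y_stress: float, grand_control_mean: float
) -> float:
    """Fernandez stress tolerance index (Y_p * Y_s) / Ybar_p**2."""
    if grand_control_mean <= 0:
        raise ValidationError("grand control mean must be positive")
    if y_control < 0 or y_stress < 0:
        raise ValidationError("trait means must be non-negative")
    return (y_control * y_stress) / grand_control_mean**2


def aggregate_sti(per_trait_stis: Sequence[float]) -> float:
    """Accession-level STI: arithmetic mean over the component STIs."""
    if len(per_trait_stis) == 0:
        raise ValidationError("cannot aggregate an empty STI list")
    return float(np.mean(per_trait_stis))


def combined_sti(sti_t1: float, sti_t2: float) -> float:
    """Combined-scope STI: arithmetic mean of the two stress-scope STIs."""
    if sti_t1 < 0 or sti_t2 < 0:
        raise ValidationError("STI values must be non-negative")
    return 0.5 * (sti_t1 + sti_t2)


def rank_by_trait(
    values: Mapping[str, float], orientation: str = "higher_is_better"
) -> dict[str, float]:
    """Rank accessions by one trait: rank 1 is best under the trait's
    orientation; ties receive the average of the spanned ranks."""
    if len(values) < 2:
        raise ValidationError("ranking needs >= 2 accessions")
    keys = list(values)
    vals = np.array([float(values[k]) for k in keys])
    if not np.isfinite(vals).all():
        raise ValidationError("non-finite trait value in ranking")
    if orientation == "higher_is_better":
        scores = -vals
    elif orientation == "lower_is_better":
        scores = vals
    else:
        raise ValidationError(f"unknown orientation {orientation!r}")
    ranks = pd.Series(scores).rank(method="average").to_numpy()
    return dict(zip(keys, ranks.tolist()))


def average_rank(ranks: Sequence[float]) -> float:
    """AR: arithmetic mean of the per-trait ranks."""
    if len(ranks) == 0:
        raise ValidationError("cannot average an empty rank list")
    return float(np.mean(ranks))


@dataclass
class RankTable:
    """Per-accession per-trait ranks, AR, STI and final rank for one scope.

    ``data`` columns: ``accession``, one ``rank_<trait>`` per ranked trait,
    ``AR``, ``STI`` and ``final_rank`` (a permutation of 1..n).
    """

    scope: str
    data: pd.DataFrame
    config: RankingConfig

    @property
    def accessions(self) -> list[str]:
        return self.data["accession"].tolist()

    def to_report_frame(self) -> pd.DataFrame:
        """Ranking-table-shaped report: accession / STI / AR / rank, ordered
        by final rank, values rounded to 2 decimals (round-half-even)."""
        out = self.data.sort_values("final_rank")[
            ["accession", "STI", "AR", "final_rank"]
        ].copy()
        out.columns = ["Accession Code", "STI", "AR", "Rank"]
        out["STI"] = out["STI"].round(2)
        out["AR"] = out["AR"].round(2)
        out["Rank"] = out["Rank"].astype(float).round(2)
        return out.reset_index(drop=True)


def _component_means(table: StudyTable, component: str) -> pd.DataFrame:
    """Accession x treatment means of one STI component.

    A '+'-joined component (e.g. ``RL+SL``) is summed per replicate before
    averaging, so every member trait must be present in each replicate.
    """
    traits = component.split("+")
    sub = table.data[table.data["trait"].isin(traits)]
    wide = sub.pivot_table(
        index=["accession", "treatment", "replicate"],
        columns="trait",
        values="value",
    )
    missing = wide.isna().any(axis=1)
    if missing.any():
        acc = wide.index[missing][0][0]
        raise ValidationError(
            f"accession {acc}: incomplete replicate for STI component "
            f"{component!r}"
        )
    summed = wide[traits].sum(axis=1)
    return (
        summed.groupby(level=["accession", "treatment"])
        .mean()
        .rename("value")
        .reset_index()
    )


def _scope_trait_values(
    means: pd.DataFrame, scope: str, trait: str
) -> pd.Series:
    """Accession -> trait value for the scope (T1, T2, or the T1/T2
    average for the combined scope)."""
    sub = means[means["trait"] == trait]
    wide = sub.pivot(index="accession", columns="treatment", values="value")
    if scope in ("T1", "T2"):
        if scope not in wide.columns or wide[scope].isna().any():
            bad = (
                wide.index[wide[scope].isna()].tolist()
                if scope in wide.columns
                else wide.index.tolist()
            )
            raise ValidationError(
                f"trait {trait}: missing {scope} data for accession(s) {bad}"
            )
        return wide[scope]
    for code in ("T1", "T2"):
        if code not in wide.columns or wide[code].isna().any():
            raise ValidationError(
                f"trait {trait}: combined scope needs complete T1 and T2 data"
            )
    return 0.5 * (wide["T1"] + wide["T2"])


def _scope_sti(
    table: StudyTable, config: RankingConfig, scope: str
) -> pd.Series:
    """Aggregate STI per accession for scope T1 or T2."""
    parts = []
    for comp in config.sti_components:
        cm = _component_means(table, comp)
        wide = cm.pivot(index="accession", columns="treatment", values="value")
        if "T0" not in wide.columns or wide["T0"].isna().any():
            raise ValidationError(
                f"STI component {comp!r}: missing control (T0) data"
            )
        if scope not in wide.columns or wide[scope].isna().any():
            raise ValidationError(
                f"STI component {comp!r}: missing {scope} data"
            )
        grand_control = float(wide["T0"].mean())
        sti = pd.Series(
            [
                compute_sti(yp, ys, grand_control)
                for yp, ys in zip(wide["T0"], wide[scope])
            ],
            index=wide.index,
        )
        parts.append(sti)
    stacked = pd.concat(parts, axis=1)
    return stacked.mean(axis=1)


def build_rank_table(
    table: StudyTable, config: RankingConfig | None = None, scope: str = "combined"
) -> RankTable:
    """Build the full per-scope ranking of all accessions.

    Per-trait values are accession means under the scope's treatment (the
    T1/T2 average for the combined scope); AR averages the per-trait ranks
    over ``config.ranked_traits``; STI aggregates Fernandez indices over
    ``config.sti_components`` (combined scope: mean of the T1 and T2
    aggregates). The final rank follows ``config.final_order_policy``
    with deterministic tie-breaks (secondary index, then accession id).
    """
    if config is None:
        config = RankingConfig()
    if scope not in SCOPES:
        raise ValidationError(f"scope must be one of {SCOPES}")
    table.require_control()
    means = accession_means(table)
    accessions = sorted(table.accessions)
    if len(accessions) < 2:
        raise ValidationError("ranking needs >= 2 accessions")

    rank_cols: dict[str, dict[str, float]] = {}
    for trait in config.ranked_traits:
        vals = _scope_trait_values(means, scope, trait)
        missing = sorted(set(accessions) - set(vals.index))
        if missing:
            raise ValidationError(
                f"trait {trait}: no data for accession(s) {missing}"
            )
        rank_cols[trait] = rank_by_trait(
            vals.to_dict(), config.orientation(trait)
        )

    if scope == "combined":
        sti_t1 = _scope_sti(table, config, "T1")
        sti_t2 = _scope_sti(table, config, "T2")
        sti = pd.Series(
            {
                acc: combined_sti(sti_t1[acc], sti_t2[acc])
                for acc in accessions
            }
        )
    else:
        sti = _scope_sti(table, config, scope)

    rows = []
    for acc in accessions:
        per_trait = [rank_cols[t][acc] for t in config.ranked_traits]
        rows.append(
            {
                "accession": acc,
                **{f"rank_{t}": rank_cols[t][acc] for t in config.ranked_traits},
                "AR": average_rank(per_trait),
                "STI": float(sti[acc]),
            }
        )
    df = pd.DataFrame(rows)

    policy = config.final_order_policy.get(
        scope, "ar_asc" if scope == "combined" else "sti_desc"
    )
    if policy == "sti_desc":
        order = df.sort_values(
            by=["STI", "AR", "accession"], ascending=[False, True, True]
        )
    else:
        order = df.sort_values(
            by=["AR", "STI", "accession"], ascending=[True, False, True]
        )
    final = pd.Series(
        np.arange(1, len(order) + 1), index=order.index, dtype=int
    )
    df["final_rank"] = final
    return RankTable(scope=scope, data=df, config=config)


@dataclass
class ToleranceClasses:
    """high / moderate / low class per accession, from the final ranking."""

    classes: dict[str, str]
    boundaries: list[int]  # final-rank upper bound (inclusive) per class
    scope: str

    def members(self, label: str) -> list[str]:
        return sorted(a for a, c in self.classes.items() if c == label)


_CLASS_LABELS = ("high", "moderate", "low")


def classify(rank_table: RankTable, n_groups: int = 3) -> ToleranceClasses:
    """Slice the final-rank ordering into near-equal contiguous groups:
    best slice = high tolerance, worst = low, middle = moderate.

    With n_groups other than 3 the labels are ``group1`` (best) .. ``groupN``.
    """
    n = len(rank_table.data)
    if n_groups < 2:
        raise ValidationError("n_groups must be >= 2")
    if n_groups > n:
        raise ValidationError("more groups than accessions")
    ordered = rank_table.data.sort_values("final_rank")["accession"].tolist()
    slices = np.array_split(np.array(ordered, dtype=object), n_groups)
    labels = (
        _CLASS_LABELS
        if n_groups == 3
        else tuple(f"group{i + 1}" for i in range(n_groups))
    )
    classes: dict[str, str] = {}
    boundaries: list[int] = []
    upper = 0
    for label, chunk in zip(labels, slices):
        upper += len(chunk)
        boundaries.append(upper)
        for acc in chunk:
            classes[str(acc)] = label
    return ToleranceClasses(
        classes=classes, boundaries=boundaries, scope=rank_table.scope
    )
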