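"""Domain model for the PEG-6000 osmotic-stress germination assay.

A screening experiment measures 12 traits on a panel of accessions grown
under a control treatment (0% PEG) and two osmotic-stress treatments
(7.5% and 15% PEG-6000), with several replicate petri dishes per cell.
This module defines the trait catalogue, the treatment levels, the
replicate-level observation table (:class:`StudyTable`), its CSV I/O, and
Table-1-style descriptive summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TraitDescriptor",
    "Treatment",
    "TREATMENTS",
    "TRAITS",
    "TRAIT_NAMES",
    "MORPHOLOGICAL",
    "BIOCHEMICAL",
    "StudyTable",
    "DescriptiveSummary",
    "compute_germination_percentage",
    "read_trait_table",
    "write_trait_table",
    "accession_means",
    "summarize",
]


@dataclass(frozen=True)
class TraitDescriptor:
    """One measured trait: name, units, category and ranking orientation.

    ``orientation`` states whether larger values indicate better stress
    performance (``higher_is_better``) or damage (``lower_is_better``);
    it is consumed by the ranking stage and can be overridden per run.
    """

    name: str
    units: str
    category: str  # "morphological" | "biochemical"
    orientation: str = "higher_is_better"

    def __post_init__(self) -> None:
        if self.category not in ("morphological", "biochemical"):
            raise ValueError(f"unknown trait category: {self.category!r}")
        if self.orientation not in ("higher_is_better", "lower_is_better"):
            raise ValueError(f"unknown orientation: {self.orientation!r}")


@dataclass(frozen=True)
class Treatment:
    """A PEG-6000 treatment level.

    ``dose`` is the stress level normalised to [0, 1]: 0 for the control,
    1 for the strongest treatment (15% PEG).
    """

    code: str
    peg_percent: float
    dose: float


TREATMENTS: tuple[Treatment, ...] = (
    Treatment("T0", 0.0, 0.0),
    Treatment("T1", 7.5, 0.5),
    Treatment("T2", 15.0, 1.0),
)

_TREATMENT_BY_CODE = {t.code: t for t in TREATMENTS}
_TREATMENT_BY_PEG = {t.peg_percent: t for t in TREATMENTS}

# Lipid peroxidation (LP, an MDA-type membrane-damage marker) is the one
# trait where accumulation signals injury rather than tolerance.
TRAITS: tuple[TraitDescriptor, ...] = (
    TraitDescriptor("GP", "%", "morphological"),
    TraitDescriptor("RL", "cm", "morphological"),
    TraitDescriptor("SL", "cm", "morphological"),
    TraitDescriptor("FW", "mg", "morphological"),
    TraitDescriptor("DW", "mg", "morphological"),
    TraitDescriptor("PC", "ug/g FW", "biochemical"),
    TraitDescriptor("SSC", "ug/g FW", "biochemical"),
    TraitDescriptor("TPC", "ug/g FW", "biochemical"),
    TraitDescriptor("AC", "ug/g FW", "biochemical"),
    TraitDescriptor("GPA", "units/min/g FW", "biochemical"),
    TraitDescriptor("CAT", "units/min/g FW", "biochemical"),
    TraitDescriptor("LP", "nmol/g FW", "biochemical", "lower_is_better"),
)

TRAIT_NAMES: tuple[str, ...] = tuple(t.name for t in TRAITS)
TRAIT_BY_NAME: dict[str, TraitDescriptor] = {t.name: t for t in TRAITS}
MORPHOLOGICAL: tuple[str, ...] = tuple(
    t.name for t in TRAITS if t.category == "morphological"
)
BIOCHEMICAL: tuple[str, ...] = tuple(
    t.name for t in TRAITS if t.category == "biochemical"
)

_COLUMNS = ["accession", "treatment", "replicate", "trait", "value"]
_KEY = ["accession", "treatment", "trait", "replicate"]


class ValidationError(ValueError):
    """Raised when an observation table violates the study design contract."""


def parse_treatment(token: object) -> Treatment:
    """Map a treatment code (``T0``/``T1``/``T2``) or a PEG percent
    (``0``/``7.5``/``15``) to its :class:`Treatment`."""
    s = str(token).strip()
    if s in _TREATMENT_BY_CODE:
        return _TREATMENT_BY_CODE[s]
    try:
        peg = float(s)
    except ValueError:
        peg = None
    if peg is not None and peg in _TREATMENT_BY_PEG:
        return _TREATMENT_BY_PEG[peg]
    raise ValidationError(
        f"unknown treatment {token!r}; expected one of "
        f"{sorted(_TREATMENT_BY_CODE)} or PEG percent in "
        f"{sorted(_TREATMENT_BY_PEG)}"
    )


def compute_germination_percentage(germinated: int, total: int) -> float:
    """Germination percentage: 100 x germinated / total sown seeds."""
    if total <= 0:
        raise ValueError("total seed count must be positive")
    if germinated < 0 or germinated > total:
        raise ValueError(
            f"germinated count {germinated} outside [0, {total}]"
        )
    return 100.0 * germinated / total


@dataclass
class StudyTable:
    """Replicate-level trait observations keyed by
    (accession, treatment, trait, replicate).

    Backed by a long-format :class:`pandas.DataFrame` with columns
    ``accession, treatment, replicate, trait, value`` (treatment stored as
    its T-code). Construction validates key uniqueness, trait names,
    finiteness/non-negativity of values and the GP range.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        df = df[_COLUMNS].copy()
        df["accession"] = df["accession"].astype(str)
        df["treatment"] = [parse_treatment(t).code for t in df["treatment"]]
        df["replicate"] = df["replicate"].astype(int)
        df["trait"] = df["trait"].astype(str)
        df["value"] = df["value"].astype(float)

        bad = sorted(set(df["trait"]) - set(TRAIT_NAMES))
        if bad:
            raise ValidationError(
                f"unknown trait name(s) {bad}; permitted traits: "
                f"{list(TRAIT_NAMES)}"
            )
        if (df["replicate"] <= 0).any():
            raise ValidationError("replicate numbers must be positive")
        if not np.isfinite(df["value"]).all():
            raise ValidationError("non-finite trait value")
        if (df["value"] < 0).any():
            raise ValidationError("trait values must be non-negative")
        gp = df.loc[df["trait"] == "GP", "value"]
        if ((gp < 0) | (gp > 100)).any():
            raise ValidationError("GP values must lie in [0, 100]")

        dup = df.duplicated(subset=_KEY)
        if dup.any():
            row = df[dup].iloc[0]
            raise ValidationError(
                "duplicate observation key "
                f"(accession={row['accession']}, treatment={row['treatment']}, "
                f"trait={row['trait']}, replicate={row['replicate']})"
            )
        self.data = df.reset_index(drop=True)

    # -- design metadata ---------------------------------------------------
    @property
    def accessions(self) -> list[str]:
        return sorted(self.data["accession"].unique())

    @property
    def treatments(self) -> list[str]:
        return sorted(self.data["treatment"].unique())

    @property
    def traits(self) -> list[str]:
        present = set(self.data["trait"])
        return [t for t in TRAIT_NAMES if t in present]

    def __len__(self) -> int:
        return len(self.data)

    def require_control(self) -> None:
        """Every accession must be observed under T0 (the STI denominator)."""
        with_control = set(
            self.data.loc[self.data["treatment"] == "T0", "accession"]
        )
        missing = sorted(set(self.accessions) - with_control)
        if missing:
            raise ValidationError(
                f"accessions without control (T0) observations: {missing}"
            )

    def subset(
        self,
        *,
        treatments: Iterable[str] | None = None,
        traits: Iterable[str] | None = None,
    ) -> "StudyTable":
        df = self.data
        if treatments is not None:
            codes = [parse_treatment(t).code for t in treatments]
            df = df[df["treatment"].isin(codes)]
        if traits is not None:
            df = df[df["trait"].isin(list(traits))]
        return StudyTable(df.copy())


def read_trait_table(path: str | Path) -> StudyTable:
    """Read a long-format CSV (``accession,treatment,replicate,trait,value``)
    into a validated :class:`StudyTable`.

    Validation failures name the offending row (1-based data row number).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"accession": str, "trait": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    # row-by-row diagnostics for unparsable fields
    for col in ("replicate", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"{path}: unparsable {col} at data row {bad[0] + 1}: "
                f"{df.loc[bad[0], col]!r}"
            )
    dup = df.duplicated(subset=_KEY)
    if dup.any():
        i = int(df.index[dup][0])
        raise ValidationError(
            f"{path}: duplicate key at data row {i + 1}: "
            f"{tuple(df.loc[i, _KEY])}"
        )
    try:
        return StudyTable(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_trait_table(table: StudyTable, path: str | Path) -> Path:
    """Write a StudyTable to CSV; round-trips through
    :func:`read_trait_table` field-for-field."""
    if len(table) == 0:
        raise ValidationError("refusing to write an empty StudyTable")
    path = Path(path)
    table.data.to_csv(path, index=False)
    return path


def accession_means(table: StudyTable) -> pd.DataFrame:
    """Mean over replicates for each (accession, treatment, trait) cell.

    Cells with no observations are simply absent (never imputed as zero).
    Returns a tidy frame with columns ``accession, treatment, trait, value``.
    """
    out = (
        table.data.groupby(["accession", "treatment", "trait"], sort=True)[
            "value"
        ]
        .mean()
        .reset_index()
    )
    return out


@dataclass(frozen=True)
class DescriptiveSummary:
    """Min/max/mean over accession-level means for one trait x treatment,
    plus the one-way (CRD) accession-effect F test on replicate values."""

    trait: str
    treatment: str
    min: float
    max: float
    mean: float
    f_statistic: float | None
    p_value: float | None
    degenerate: bool = False


def summarize(table: StudyTable, trait: str, treatment: str) -> DescriptiveSummary:
    """Table-1-style descriptive summary of one trait under one treatment.

    min/max/mean are over accession means; F and p come from a one-way
    completely-randomised-design ANOVA with accession as the factor, run on
    the replicate-level values. Designs with a single accession are
    rejected; an all-constant trait yields a not-computable flag.
    """
    from .anova import one_way_anova  # local import avoids a cycle

    code = parse_treatment(treatment).code
    sub = table.data[(table.data["trait"] == trait) & (table.data["treatment"] == code)]
    if sub.empty:
        raise ValidationError(f"no observations for trait {trait} under {code}")
    groups = [g["value"].to_numpy() for _, g in sub.groupby("accession")]
    if len(groups) < 2:
        raise ValidationError(
            "descriptive summary needs at least 2 accessions"
        )
    means = np.array([g.mean() for g in groups])
    if all(len(g) >= 2 for g in groups):
        tab = one_way_anova(groups, factor="accession")
        row = tab.row("accession")
        if tab.degenerate and not np.isfinite(row.F):
            f_stat, p_val, degen = None, None, True
        else:
            f_stat, p_val, degen = row.F, row.p, tab.degenerate
    else:  # un-replicated cells: no error term
        f_stat, p_val, degen = None, None, True
    return DescriptiveSummary(
        trait=trait,
        treatment=code,
        min=float(means.min()),
        max=float(means.max()),
        mean=float(means.mean()),
        f_statistic=f_stat,
        p_value=p_val,
        degenerate=degen,
    )
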