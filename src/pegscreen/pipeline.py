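"""Orchestration of the full screening workflow and report emission.

One call runs every stage on a study table (read from CSV or freshly
simulated): descriptive summaries, per-trait two-way ANOVA, the three rank
tables (T1, T2, combined), tolerance classes and the biomarker report.
Reports are CSV files; values are rounded to 2 decimals (round-half-even)
at emission only and p-values below 1e-4 are printed as ``<0.0001`` —
internally everything is kept at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import two_way_anova
from .biomarkers import BiomarkerReport, identify_biomarkers
from .ranking import (
    RankingConfig,
    RankTable,
    ToleranceClasses,
    build_rank_table,
    classify,
)
from .simulate import GeneratorConfig, default_paper_like_config, generate
from .traits import (
    StudyTable,
    TREATMENTS,
    ValidationError,
    read_trait_table,
    summarize,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "PipelineResult",
    "run_full_pipeline",
    "load_ranking_config",
]


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass
class PipelineConfig:
    """Exactly one input source (CSV path xor generator config)."""

    input_path: Path | None = None
    generator: GeneratorConfig | None = None
    ranking: RankingConfig = field(default_factory=RankingConfig)
    alpha_letters: float = 0.01
    alpha_stars: float = 0.001
    outdir: Path = Path("pegscreen_out")

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValidationError(
                "configure exactly one input source: a CSV path or a "
                "generator config"
            )


@dataclass
class PipelineResult:
    table: StudyTable
    summaries: pd.DataFrame
    anova: pd.DataFrame
    rank_tables: dict[str, RankTable]
    classes: ToleranceClasses
    biomarker_report: BiomarkerReport
    outdir: Path


def load_ranking_config(path: str | Path) -> RankingConfig:
    """Read a YAML ranking config (trait orientations and trait sets).

    Keys (all optional): ``ranked_traits`` (list), ``sti_components``
    (list, '+'-joined names are summed), ``orientations`` (trait -> value),
    ``final_order_policy`` (scope -> sti_desc|ar_asc).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "ranked_traits" in raw:
        kwargs["ranked_traits"] = tuple(raw["ranked_traits"])
    if "sti_components" in raw:
        kwargs["sti_components"] = tuple(raw["sti_components"])
    if "orientations" in raw:
        kwargs["orientation_overrides"] = dict(raw["orientations"])
    if "final_order_policy" in raw:
        base = dict(RankingConfig().final_order_policy)
        base.update(raw["final_order_policy"])
        kwargs["final_order_policy"] = base
    return RankingConfig(**kwargs)


def format_p(p: float | None) -> str:
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return "NA"
    if p < 1e-4:
        return "<0.0001"
    return f"{p:.4f}"


def _stars(p: float | None, alpha_stars: float) -> str:
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return ""
    return "***" if p <= alpha_stars else ""


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name}: {exc}") from exc
            return False

    return _Ctx()


def summarize_all(table: StudyTable) -> pd.DataFrame:
    """Descriptive-statistics report: one row per trait x treatment."""
    rows = []
    for treatment in TREATMENTS:
        if treatment.code not in table.treatments:
            continue
        for trait in table.traits:
            s = summarize(table, trait, treatment.code)
            rows.append(
                {
                    "treatment": s.treatment,
                    "trait": s.trait,
                    "min": s.min,
                    "max": s.max,
                    "mean": s.mean,
                    "F": s.f_statistic,
                    "p": s.p_value,
                    "degenerate": s.degenerate,
                }
            )
    return pd.DataFrame(rows)


def anova_all(table: StudyTable, alpha_stars: float = 0.001) -> pd.DataFrame:
    """Two-way ANOVA report: per trait, the mean square and p of the
    accession, PEG and interaction effects, with significance stars."""
    rows = []
    for trait in table.traits:
        tab = two_way_anova(table, trait)
        row: dict = {"trait": trait}
        for source, label in (
            ("accession", "accession"),
            ("peg", "peg"),
            ("accession:peg", "interaction"),
        ):
            r = tab.row(source)
            row[f"MS_{label}"] = r.ms
            row[f"p_{label}"] = r.p
            row[f"sig_{label}"] = _stars(r.p, alpha_stars)
        row["MS_error"] = tab.row("error").ms
        row["degenerate"] = tab.degenerate
        rows.append(row)
    return pd.DataFrame(rows)


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle under ``config.outdir``.

    Deterministic for a fixed generator seed: running twice produces
    byte-identical report CSVs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    with _stage("input"):
        if config.input_path is not None:
            table = read_trait_table(config.input_path)
        else:
            table, truth = generate(config.generator)

    with _stage("descriptive_summary"):
        summaries = summarize_all(table)

    with _stage("two_way_anova"):
        anova = anova_all(table, config.alpha_stars)

    with _stage("sti_ranking"):
        table.require_control()
        rank_tables = {
            scope: build_rank_table(table, config.ranking, scope)
            for scope in ("T1", "T2", "combined")
        }

    with _stage("tolerance_classes"):
        classes = classify(rank_tables["combined"])

    with _stage("biomarkers"):
        report = identify_biomarkers(
            table, classes, alpha=config.alpha_letters
        )

    with _stage("emit_reports"):
        _emit(config, table, summaries, anova, rank_tables, classes, report,
              truth, outdir)

    return PipelineResult(
        table=table,
        summaries=summaries,
        anova=anova,
        rank_tables=rank_tables,
        classes=classes,
        biomarker_report=report,
        outdir=outdir,
    )


def _round2(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(2)
    return out


def _emit(config, table, summaries, anova, rank_tables, classes, report,
          truth, outdir: Path) -> None:
    summ = _round2(summaries.drop(columns=["p"]))
    summ["p"] = [format_p(p) for p in summaries["p"]]
    summ.to_csv(outdir / "descriptive_summary.csv", index=False)

    an = _round2(anova.drop(columns=[c for c in anova.columns if c.startswith("p_")]))
    for label in ("accession", "peg", "interaction"):
        an[f"p_{label}"] = [format_p(p) for p in anova[f"p_{label}"]]
    an.to_csv(outdir / "anova_two_way.csv", index=False)

    for scope, rt in rank_tables.items():
        rt.to_report_frame().to_csv(
            outdir / f"rank_{scope}.csv", index=False
        )

    cls = pd.DataFrame(
        sorted(classes.classes.items()), columns=["accession", "class"]
    )
    cls.to_csv(outdir / "tolerance_classes.csv", index=False)

    bm = report.to_frame()
    bm_fmt = _round2(bm.drop(columns=["p_value"]))
    bm_fmt.insert(2, "p_value", [format_p(p) for p in bm["p_value"]])
    bm_fmt.to_csv(outdir / "biomarkers.csv", index=False)

    if truth is not None:
        truth.to_frame().to_csv(outdir / "ground_truth.csv", index=False)

    lines = [
        f"pegscreen {__version__}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"input: {config.input_path or 'generator'}",
        f"generator: {config.generator}",
        f"ranking: {config.ranking}",
        f"alpha_letters: {config.alpha_letters}",
        f"alpha_stars: {config.alpha_stars}",
        f"n_observations: {len(table)}",
        f"biomarkers: {report.biomarkers}",
    ]
    (outdir / "run_log.txt").write_text("\n".join(lines) + "\n")
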