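"""Synthetic study-table generator with planted tolerance structure.

The generator emulates the screening design — a panel of accessions, three
PEG-6000 levels (doses 0 / 0.5 / 1), replicated petri dishes, 12 traits —
with the statistical structure the downstream analysis assumes:

* a mild multiplicative (lognormal) genotype effect per accession x trait;
* a dose response per trait: germination and seedling growth decline with
  dose, dry weight and the biochemical pools accumulate;
* a single latent tolerance score per accession in [0, 1] that attenuates
  the morphological decline and amplifies the biochemical accumulation
  (lipid peroxidation, a damage marker, is amplified by *sensitivity*,
  1 - tolerance, instead);
* truncated-at-zero normal replicate noise with a per-trait CV; GP is
  drawn as a binomial germination count out of ``seeds_per_dish``.

The expected cell mean for accession *i*, trait *t*, dose *s* is

    mu_t * g_it * (1 - d_t * s * (1 - e_t * tol_i))      (declining traits)
    mu_t * g_it * (1 + u_t * s * (1 + e_t * tol_i))      (accumulating)

with e_t = tolerance_effect x per-trait signal weight. Dose multipliers
are calibrated so that at the mean tolerance score (0.5) the dose-1 grand
mean over accessions hits the configured stress/control mean ratio.

Ground-truth scores and classes are returned alongside the table so
recovery tests can compare planted against recovered structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .ranking import ToleranceClasses
from .traits import (
    MORPHOLOGICAL,
    TRAIT_NAMES,
    StudyTable,
    Treatment,
    TREATMENTS,
    ValidationError,
)

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "default_paper_like_config"]

#: control-condition grand means per trait (units as in the trait catalogue)
CONTROL_BASELINES: dict[str, float] = {
    "GP": 90.10,
    "RL": 8.21,
    "SL": 7.08,
    "FW": 47.35,
    "DW": 1.95,
    "PC": 854.45,
    "SSC": 129.97,
    "TPC": 78.33,
    "AC": 557.82,
    "GPA": 0.20,
    "CAT": 88.88,
    "LP": 4.55,
}

#: grand-mean ratio (full stress / control) per trait. GP, RL, SL and FW
#: decline; DW and the biochemical pools accumulate under osmotic stress.
STRESS_RATIOS: dict[str, float] = {
    "GP": 80.04 / 90.10,
    "RL": 4.65 / 8.21,
    "SL": 3.63 / 7.08,
    "FW": 30.25 / 47.35,
    "DW": 3.08 / 1.95,
    "PC": 2295.87 / 854.45,
    "SSC": 220.88 / 129.97,
    "TPC": 389.86 / 78.33,
    "AC": 732.29 / 557.82,
    "GPA": 0.40 / 0.20,
    "CAT": 178.77 / 88.88,
    "LP": 6.39 / 4.55,
}

#: traits whose grand mean declines with dose (everything else accumulates)
DECLINING_TRAITS: tuple[str, ...] = ("GP", "RL", "SL", "FW")


@dataclass(frozen=True)
class GeneratorConfig:
    """Design sizes, trait calibration and noise levels of the generator."""

    n_accessions: int = 64
    n_reps: int = 5
    seeds_per_dish: int = 25
    seed: int = 2024
    baselines: Mapping[str, float] = field(
        default_factory=lambda: dict(CONTROL_BASELINES)
    )
    stress_ratios: Mapping[str, float] = field(
        default_factory=lambda: dict(STRESS_RATIOS)
    )
    #: strength with which the latent tolerance score modulates the dose
    #: response (0 = no genotype x treatment interaction)
    tolerance_effect: float = 1.0
    #: per-trait multiplier on tolerance_effect (set a trait to 0 to
    #: silence its tolerance signal, e.g. for biomarker recovery tests)
    signal_weights: Mapping[str, float] = field(
        default_factory=lambda: {t: 1.0 for t in TRAIT_NAMES}
    )
    #: replicate-level coefficient of variation (non-GP traits)
    noise_cv: float = 0.02
    #: sd of the lognormal genotype effect (log scale)
    genotype_sd: float = 0.01
    #: planted tolerance scores: "even" spacing over [0, 1] assigned in a
    #: seed-determined permutation, or an explicit accession -> score map
    tolerance_scores: Mapping[str, float] | str = "even"

    def __post_init__(self) -> None:
        if self.n_accessions < 2 or self.n_reps < 1:
            raise ValidationError("need >= 2 accessions and >= 1 replicate")
        if self.seeds_per_dish < 1:
            raise ValidationError("seeds_per_dish must be >= 1")
        if self.noise_cv < 0 or self.genotype_sd < 0:
            raise ValidationError("noise levels must be non-negative")
        for t in TRAIT_NAMES:
            if self.baselines.get(t, 0) <= 0:
                raise ValidationError(f"baseline mean for {t} must be positive")
            if self.stress_ratios.get(t, 0) <= 0:
                raise ValidationError(f"stress ratio for {t} must be positive")

    def coupling(self, trait: str) -> float:
        return self.tolerance_effect * self.signal_weights.get(trait, 1.0)

    def dose_multiplier(self, trait: str) -> float:
        """Calibrated dose coefficient d_t (declining) or u_t (accumulating),
        anchored at the mean tolerance score 0.5."""
        r = self.stress_ratios[trait]
        e = self.coupling(trait)
        if trait in DECLINING_TRAITS:
            denom = 1.0 - 0.5 * e
            d = (1.0 - r) / denom
            if d * (1.0 - 0.0) >= 1.0:  # most sensitive accession at dose 1
                raise ValidationError(
                    f"dose response for {trait} drives expected means negative"
                )
            return d
        return (r - 1.0) / (1.0 + 0.5 * e)

    def expected_multiplier(self, trait: str, dose: float, tol: float) -> float:
        """Closed-form expected (mean) dose multiplier for one accession."""
        e = self.coupling(trait)
        if trait in DECLINING_TRAITS:
            return 1.0 - self.dose_multiplier(trait) * dose * (1.0 - e * tol)
        if trait == "LP":
            return 1.0 + self.dose_multiplier(trait) * dose * (1.0 + e * (1.0 - tol))
        return 1.0 + self.dose_multiplier(trait) * dose * (1.0 + e * tol)


@dataclass
class GroundTruth:
    """Planted tolerance scores and their tertile classes."""

    scores: dict[str, float]
    classes: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accession": list(self.scores),
                "tolerance_score": list(self.scores.values()),
                "class": [self.classes[a] for a in self.scores],
            }
        )

    def as_tolerance_classes(self) -> ToleranceClasses:
        return ToleranceClasses(
            classes=dict(self.classes), boundaries=[], scope="truth"
        )


def default_paper_like_config(seed: int = 2024) -> GeneratorConfig:
    """The calibrated default design: 64 accessions x 3 treatments x
    5 replicates x 12 traits, 25 seeds per dish, strong tolerance effect.

    Pure: two calls with the same seed return identical configs.
    """
    return GeneratorConfig(seed=seed)


def _tolerance_scores(
    config: GeneratorConfig, accessions: list[str], rng: np.random.Generator
) -> dict[str, float]:
    if isinstance(config.tolerance_scores, str):
        if config.tolerance_scores != "even":
            raise ValidationError(
                f"unknown tolerance score policy {config.tolerance_scores!r}"
            )
        spaced = (
            np.linspace(0.0, 1.0, len(accessions))
            if len(accessions) > 1
            else np.array([0.5])
        )
        perm = rng.permutation(len(accessions))
        return {accessions[i]: float(spaced[perm[i]]) for i in range(len(accessions))}
    scores = {str(a): float(s) for a, s in config.tolerance_scores.items()}
    if set(scores) != set(accessions):
        raise ValidationError("tolerance_scores must cover every accession")
    if any(not 0.0 <= s <= 1.0 for s in scores.values()):
        raise ValidationError("tolerance scores must lie in [0, 1]")
    return scores


def _tertile_classes(scores: dict[str, float]) -> dict[str, str]:
    order = sorted(scores, key=lambda a: (-scores[a], a))
    chunks = np.array_split(np.array(order, dtype=object), 3)
    labels = ("high", "moderate", "low")
    out: dict[str, str] = {}
    for label, chunk in zip(labels, chunks):
        for acc in chunk:
            out[str(acc)] = label
    return out


def _truncated_normal(
    rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    """Normal draws truncated at zero (resampling; truncation mass is tiny
    at the default CV so a few passes suffice)."""
    out = rng.normal(mean, sd)
    for _ in range(100):
        neg = out < 0
        if not neg.any():
            return out
        out[neg] = rng.normal(mean[neg], sd[neg])
    return np.maximum(out, 0.0)


def generate(config: GeneratorConfig | None = None) -> tuple[StudyTable, GroundTruth]:
    """Draw one synthetic study table plus its ground truth.

    Deterministic: identical configs (including seed) give identical
    output.
    """
    if config is None:
        config = default_paper_like_config()
    rng = np.random.default_rng(config.seed)
    n = config.n_accessions
    width = len(str(n))
    accessions = [f"AC{i + 1}" for i in range(n)]
    scores = _tolerance_scores(config, accessions, rng)
    truth = GroundTruth(scores=scores, classes=_tertile_classes(scores))

    # genotype effects: one lognormal factor per accession x trait
    g = np.exp(
        rng.normal(0.0, config.genotype_sd, size=(n, len(TRAIT_NAMES)))
    )
    tol = np.array([scores[a] for a in accessions])

    reps = config.n_reps
    acc_col = np.repeat(np.array(accessions, dtype=object), reps)
    rep_col = np.tile(np.arange(1, reps + 1), n)
    blocks: list[pd.DataFrame] = []
    for ti, trait in enumerate(TRAIT_NAMES):
        mu = config.baselines[trait]
        for treatment in TREATMENTS:
            mult = np.array(
                [
                    config.expected_multiplier(trait, treatment.dose, t)
                    for t in tol
                ]
            )
            cell_mean = mu * g[:, ti] * mult  # per accession
            if (cell_mean <= 0).any():
                raise ValidationError(
                    f"negative expected mean for {trait} under {treatment.code}"
                )
            if trait == "GP":
                p = np.clip(cell_mean / 100.0, 0.0, 1.0)
                counts = rng.binomial(
                    config.seeds_per_dish, np.repeat(p, reps)
                )
                values = 100.0 * counts / config.seeds_per_dish
            else:
                means = np.repeat(cell_mean, reps)
                if config.noise_cv == 0:
                    values = means.copy()
                else:
                    values = _truncated_normal(
                        rng, means, config.noise_cv * means
                    )
            blocks.append(
                pd.DataFrame(
                    {
                        "accession": acc_col,
                        "treatment": treatment.code,
                        "replicate": rep_col,
                        "trait": trait,
                        "value": values.astype(float),
                    }
                )
            )
    table = StudyTable(pd.concat(blocks, ignore_index=True))
    return table, truth
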