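"""Longitudinal cohort containers and tidy-text I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "subtype",
    "sex",
    "age_at_baseline",
    "age_at_diagnosis",
]
OBS_COLUMNS = ["subject_id", "time", "outcome", "value"]


@dataclass(frozen=True)
class OutcomeSpec:
    """Declaration of a clinical outcome scale.

    ``mean_slope`` and ``noise_sd`` are expressed on the min-max
    normalized [0, 1] scale after direction harmonization (positive
    slope = worsening). ``accel_loading`` couples the individual slope
    to the subject's latent accelerated-aging factor (normalized units
    per year, per year of the factor); it is what makes some domains
    prognostically linked to brain aging in simulation.
    """

    name: str
    theoretical_min: float
    theoretical_max: float
    direction: str = "higher_worse"  # or "higher_better"
    mean_slope: float = 0.03
    noise_sd: float = 0.03
    domain: str = "clinical"  # cognitive | motor | clinical | imaging | fluid
    accel_loading: float = 0.0

    def __post_init__(self):
        if not self.theoretical_min < self.theoretical_max:
            raise ValueError(f"{self.name}: theoretical_min must be < theoretical_max")
        if self.direction not in ("higher_worse", "higher_better"):
            raise ValueError(f"{self.name}: unknown direction {self.direction!r}")
        if self.mean_slope <= 0:
            raise ValueError(f"{self.name}: mean_slope must be > 0 after harmonization")

    @property
    def span(self) -> float:
        return self.theoretical_max - self.theoretical_min


@dataclass
class LongCohort:
    """Tidy longitudinal observations plus per-subject covariates.

    ``subjects`` has one row per subject (columns ``SUBJECT_COLUMNS``);
    ``observations`` is long-format (columns ``OBS_COLUMNS``) with
    ``time`` in years since diagnosis for PD and since enrollment for HC.
    """

    subjects: pd.DataFrame
    observations: pd.DataFrame
    normalized: bool = False
    norm_maps: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(SUBJECT_COLUMNS) - set(self.subjects.columns)
        if missing:
            raise ValueError(f"subjects table missing columns: {sorted(missing)}")
        missing = set(OBS_COLUMNS) - set(self.observations.columns)
        if missing:
            raise ValueError(f"observations table missing columns: {sorted(missing)}")

    @property
    def outcome_names(self) -> list[str]:
        return sorted(self.observations["outcome"].unique())

    def subset(self, subject_ids: Iterable[str]) -> "LongCohort":
        ids = set(subject_ids)
        return LongCohort(
            subjects=self.subjects[self.subjects.subject_id.isin(ids)].reset_index(drop=True),
            observations=self.observations[
                self.observations.subject_id.isin(ids)
            ].reset_index(drop=True),
            normalized=self.normalized,
            norm_maps=dict(self.norm_maps),
        )

    def pd_subjects(self) -> pd.DataFrame:
        return self.subjects[self.subjects.group == "PD"].reset_index(drop=True)

    def baseline_table(self) -> pd.DataFrame:
        """Earliest visit per subject x outcome, wide format."""
        obs = self.observations.sort_values("time")
        first = obs.groupby(["subject_id", "outcome"], sort=False).first().reset_index()
        wide = first.pivot(index="subject_id", columns="outcome", values="value")
        return wide.reset_index().merge(self.subjects, on="subject_id", how="left")

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(directory / "subjects.tsv", sep="\t", index=False)
        self.observations.to_csv(directory / "observations.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, directory) -> "LongCohort":
        directory = Path(directory)
        subjects = pd.read_csv(directory / "subjects.tsv", sep="\t")
        observations = pd.read_csv(directory / "observations.tsv", sep="\t")
        return cls(subjects=subjects, observations=observations)


def specs_by_name(specs: Iterable[OutcomeSpec]) -> Mapping[str, OutcomeSpec]:
    return {s.name: s for s in specs}


def harmonized_value(spec: OutcomeSpec, normalized_value):
    """Map a harmonized [0,1] severity value back to the raw scale."""
    v = np.asarray(normalized_value, dtype=float)
    if spec.direction == "higher_better":
        v = 1.0 - v
    return spec.theoretical_min + v * spec.span
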