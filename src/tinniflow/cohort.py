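"""Synthetic longitudinal cohort generator.

Emulates the two-group (RI+ / RI−), four-timepoint study cohort: each
subject's 4-vector per outcome is drawn from a multivariate normal with the
published per-cell means and SDs and a compound-symmetry within-subject
correlation ``rho``, then discretized to the instrument resolution (5-dB
audiometric grid for TLL/MML, even integers for THI, 0.1 for VAS) and
clamped to the scale range.  A configurable number of RI+ subjects are
"resolved" at month 6 — their TLL and MML are set to 0, mirroring how the
study coded subjects whose tinnitus disappeared; their THI/VAS values
remain as drawn.

Clamping order is fixed (draw -> round to grid -> clamp) so results are
bit-reproducible from the seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from . import _tables
from ._tables import GROUP_NEG, GROUP_POS, GROUPS, OUTCOMES, TIMEPOINTS
from .audiogram import Audiogram


@dataclass
class CohortConfig:
    """Cohort-generator parameters; defaults reproduce the study conditions."""

    n_pos: int = _tables.N_POS
    n_neg: int = _tables.N_NEG
    outcome_params: dict = field(
        default_factory=lambda: copy.deepcopy(_tables.OUTCOME_PARAMS)
    )
    rho: float = 0.5
    n_resolved_pos: int = _tables.N_RESOLVED_POS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("each group needs at least 2 subjects")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if not (0 <= self.n_resolved_pos <= self.n_pos):
            raise ValueError("n_resolved_pos must be in [0, n_pos]")
        for group, per_outcome in self.outcome_params.items():
            for outcome, cells in per_outcome.items():
                if len(cells) != len(TIMEPOINTS):
                    raise ValueError(f"{group}/{outcome}: need one (mean, sd) per timepoint")
                if any(sd <= 0 for _, sd in cells):
                    raise ValueError(f"{group}/{outcome}: SDs must be positive")

    @property
    def outcomes(self) -> tuple[str, ...]:
        return tuple(self.outcome_params[GROUP_POS])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class LongitudinalRecord:
    """One subject: group label, demographics and per-outcome 4-vectors."""

    subject_id: str
    group: str
    age_years: int
    outcomes: dict[str, np.ndarray]
    resolved_at_month6: bool = False


def _cs_covariance(sds: np.ndarray, rho: float) -> np.ndarray:
    """Compound-symmetry covariance from per-timepoint SDs."""
    t = sds.size
    corr = np.full((t, t), rho)
    np.fill_diagonal(corr, 1.0)
    return np.outer(sds, sds) * corr


def draw_outcome_matrix(
    rng: np.random.Generator,
    cells: Iterable[tuple[float, float]],
    n: int,
    rho: float,
) -> np.ndarray:
    """Raw (undiscretized) n x T multivariate-normal draws for one
    group/outcome with compound-symmetry correlation."""
    means = np.array([m for m, _ in cells], dtype=float)
    sds = np.array([s for _, s in cells], dtype=float)
    cov = _cs_covariance(sds, rho)
    return rng.multivariate_normal(means, cov, size=n, method="cholesky")


def discretize(values: np.ndarray, outcome: str) -> np.ndarray:
    """Round to the instrument grid and clamp to the scale range.

    TLL/MML -> 5-dB grid, floor 0; THI -> even integers in [0, 100];
    VAS -> 0.1 resolution in [0, 10].
    """
    x = np.asarray(values, dtype=float)
    if outcome in ("TLL", "MML"):
        return np.clip(np.round(x / 5.0) * 5.0, 0.0, None)
    if outcome == "THI":
        return np.clip(np.round(x / 2.0) * 2.0, 0.0, 100.0)
    if outcome.startswith("VAS"):
        return np.clip(np.round(x, 1), 0.0, 10.0)
    raise ValueError(f"unknown outcome {outcome!r}")


def simulate_cohort(config: CohortConfig) -> list[LongitudinalRecord]:
    """Draw the full two-group longitudinal cohort.

    Reproducible from ``config.seed``; outcome draws, the resolved-subject
    choice and ages use independent named substreams so each is stable
    under changes to the others.
    """
    ss = np.random.SeedSequence(config.seed)
    ss_outcomes, ss_resolution, ss_ages = ss.spawn(3)
    rng_out = np.random.default_rng(ss_outcomes)
    rng_res = np.random.default_rng(ss_resolution)
    rng_age = np.random.default_rng(ss_ages)

    records: list[LongitudinalRecord] = []
    month6 = TIMEPOINTS.index("month6")
    for group, n in ((GROUP_POS, config.n_pos), (GROUP_NEG, config.n_neg)):
        per_outcome = {}
        for outcome, cells in config.outcome_params[group].items():
            raw = draw_outcome_matrix(rng_out, cells, n, config.rho)
            per_outcome[outcome] = discretize(raw, outcome)
        mean_age, sd_age, (lo, hi) = _tables.AGE_PARAMS[group]
        ages = np.clip(np.round(rng_age.normal(mean_age, sd_age, size=n)), lo, hi)
        tag = "pos" if group == GROUP_POS else "neg"
        for i in range(n):
            records.append(
                LongitudinalRecord(
                    subject_id=f"{tag}{i + 1:03d}",
                    group=group,
                    age_years=int(ages[i]),
                    outcomes={k: v[i].copy() for k, v in per_outcome.items()},
                )
            )

    pos_records = [r for r in records if r.group == GROUP_POS]
    resolved_idx = rng_res.choice(len(pos_records), size=config.n_resolved_pos, replace=False)
    for i in resolved_idx:
        rec = pos_records[i]
        rec.resolved_at_month6 = True
        for outcome in ("TLL", "MML"):
            if outcome in rec.outcomes:
                rec.outcomes[outcome][month6] = 0.0
    return records


def simulate_audiograms(
    config: CohortConfig, seed: int | None = None
) -> list[tuple[str, Audiogram]]:
    """Per-subject audiograms drawn from the published group thresholds.

    Per-frequency Gaussian draws truncated to [-10, 90] dB HL (the
    inclusion range) and rounded to the 5-dB audiometric grid.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out: list[tuple[str, Audiogram]] = []
    for group, n in ((GROUP_POS, config.n_pos), (GROUP_NEG, config.n_neg)):
        params = _tables.HEARING_THRESHOLD_PARAMS[group]
        freqs = tuple(params)
        means = np.array([params[f][0] for f in freqs])
        sds = np.array([params[f][1] for f in freqs])
        draws = rng.normal(means, sds, size=(n, len(freqs)))
        draws = np.clip(np.round(draws / 5.0) * 5.0, -10.0, 90.0)
        for i in range(n):
            out.append((group, Audiogram(freqs, tuple(draws[i]))))
    return out


def to_frame(records: list[LongitudinalRecord]) -> pd.DataFrame:
    """Tidy long format: one row per subject x timepoint x outcome."""
    rows = []
    for rec in records:
        for outcome, values in rec.outcomes.items():
            for time, value in zip(TIMEPOINTS, values):
                rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "group": rec.group,
                        "time": time,
                        "outcome": outcome,
                        "value": float(value),
                    }
                )
    return pd.DataFrame(rows)


def write_tsv(records: list[LongitudinalRecord], path: str | Path) -> None:
    to_frame(records).to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"subject_id", "group", "time", "outcome", "value"}
    if not expected.issubset(df.columns):
        raise ValueError(f"cohort TSV must have columns {sorted(expected)}")
    return df
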