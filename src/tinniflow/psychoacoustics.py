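"""Simulated tinnitus psychoacoustic assessment battery.

Implements the four clinical procedures — pitch matching, tinnitus loudness
level (TLL), minimum masking level (MML) and the residual inhibition (RI)
test — as algorithms runnable against a :class:`VirtualListener`, plus THI
questionnaire scoring.

The virtual listener is a minimal standard psychophysical observer: on each
two-alternative trial it picks the option whose attribute is closer to its
ground truth, with Gaussian internal comparison noise, and with probability
``lapse_prob`` it responds uniformly at random.  Pitch comparisons are made
in log-frequency; one octave is treated as 10 "dB-equivalent" units so a
single ``comparison_noise_db`` parameter governs both level and pitch
judgements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .audiogram import Audiogram

#: Half-octave frequency grid anchored at 125 Hz.  The top grid point is
#: 16 kHz (the last half-octave step not exceeding the 20 kHz test bound).
PITCH_GRID_HZ: tuple[float, ...] = tuple(125.0 * 2.0 ** (k / 2.0) for k in range(15))

#: Audiometer level resolution (dB) and staircase cap.
LEVEL_STEP_DB = 5.0
MAX_LEVEL_DB = 120.0

#: Contralateral presentation level for pitch matching (recorded only).
CONTRALATERAL_DB_SL = 30.0

#: Same value must be chosen this many times to terminate a procedure.
N_CHOICES_TO_TERMINATE = 3

MAX_TRIALS = 200

#: Octave-to-"dB-equivalent" scale for pitch comparison noise.
OCTAVE_AS_DB = 10.0


class ConvergenceError(RuntimeError):
    """A staircase failed to terminate within the trial cap."""


class UnmaskableError(RuntimeError):
    """Tinnitus was never masked below the maximum presentation level."""


@dataclass
class VirtualListener:
    """Ground-truth tinnitus percept plus response-noise parameters."""

    true_pitch_hz: float = 6000.0
    true_loudness_db_sl: float = 20.0
    true_masking_db: float = 35.0
    ri_positive: bool = True
    thresholds: Optional[Audiogram] = None
    lapse_prob: float = 0.0
    comparison_noise_db: float = 0.0
    tinnitus_present: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse_prob <= 1.0):
            raise ValueError("lapse_prob must be in [0, 1]")
        if self.comparison_noise_db < 0:
            raise ValueError("comparison noise SD must be >= 0")

    @classmethod
    def from_json(cls, path) -> "VirtualListener":
        with open(path) as fh:
            raw = json.load(fh)
        if "thresholds" in raw and raw["thresholds"] is not None:
            raw["thresholds"] = Audiogram(**raw["thresholds"])
        return cls(**raw)


@dataclass
class ProcedureTrace:
    """Ordered (stimulus descriptor, response) log plus the final outcome."""

    procedure: str
    steps: list[tuple[dict, object]] = field(default_factory=list)
    outcome: object = None

    def record(self, stimulus: dict, response: object) -> None:
        self.steps.append((stimulus, response))

    def to_dict(self) -> dict:
        return {
            "procedure": self.procedure,
            "steps": [{"stimulus": s, "response": r} for s, r in self.steps],
            "outcome": self.outcome,
        }


@dataclass(frozen=True)
class RIStatus:
    """Residual-inhibition classification: perception decreased -> positive;
    unchanged or increased -> negative."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError("RI status is 'positive' or 'negative'")

    @property
    def is_positive(self) -> bool:
        return self.label == "positive"


def _choose(
    listener: VirtualListener,
    rng: np.random.Generator,
    da: float,
    db: float,
) -> int:
    """2AFC decision from precomputed perceptual distances (dB-equivalent):
    index (0 or 1) of the closer option, corrupted by internal noise;
    lapses respond at random.  Ties go to the first (lower) option."""
    if rng.random() < listener.lapse_prob:
        return int(rng.integers(2))
    if listener.comparison_noise_db > 0:
        da = da + rng.normal(0.0, listener.comparison_noise_db)
        db = db + rng.normal(0.0, listener.comparison_noise_db)
    return 0 if da <= db else 1


def pitch_match(
    listener: VirtualListener, seed: int | None = None
) -> tuple[float, ProcedureTrace]:
    """Adaptive 2AFC tinnitus pitch match on the half-octave grid.

    The first pair is 0.5/4 kHz.  After each choice the chosen frequency is
    paired against the frequency one octave further in the direction of the
    choice; once the listener rejects a step (or the grid boundary is hit)
    the procedure continues in half-octave increments, bracketing the
    percept.  It terminates when the same frequency has been re-chosen
    against three (not necessarily consecutive) alternatives and returns
    that frequency; choices that move to a new frequency do not count, so
    the percept's neighborhood is always probed before termination.

    Raises
    ------
    ConvergenceError
        If no frequency reaches three re-choices within 200 trials.
    """
    if not listener.tinnitus_present:
        raise ValueError("pitch matching requires a present tinnitus percept")
    rng = np.random.default_rng(seed)
    grid = PITCH_GRID_HZ
    trace = ProcedureTrace("pitch_match")
    counts: dict[int, int] = {}
    # target position in half-octave grid units, snapped to the grid when
    # the true pitch lies on it (keeps equidistant pairs an exact tie)
    xt = 2.0 * np.log2(listener.true_pitch_hz / grid[0])
    if abs(xt - round(xt)) < 1e-9:
        xt = float(round(xt))
    half_octave_db = OCTAVE_AS_DB / 2.0

    def present(i: int, j: int) -> int:
        lo, hi = min(i, j), max(i, j)
        pick = _choose(
            listener, rng, abs(lo - xt) * half_octave_db, abs(hi - xt) * half_octave_db
        )
        chosen = lo if pick == 0 else hi
        trace.record(
            {
                "pair_hz": [round(grid[lo], 2), round(grid[hi], 2)],
                "contralateral_db_sl": CONTRALATERAL_DB_SL,
                "tone_duration_s": 1.0,
            },
            round(grid[chosen], 2),
        )
        return chosen

    i_500, i_4000 = grid.index(500.0), grid.index(4000.0)
    current = present(i_500, i_4000)
    direction = 1 if current == i_4000 else -1
    step = 2  # grid units: 2 = one octave, 1 = half octave

    for _ in range(MAX_TRIALS - 1):
        cand = current + direction * step
        cand_clipped = min(max(cand, 0), len(grid) - 1)
        if cand_clipped == current:
            # at a grid boundary: refine the step, then reverse
            if step == 2:
                step = 1
            else:
                direction = -direction
            continue
        chosen = present(current, cand_clipped)
        if chosen == cand_clipped:
            current = cand_clipped
        else:
            # candidate rejected: the incumbent was re-chosen; bracket back
            # in half-octaves
            counts[current] = counts.get(current, 0) + 1
            if counts[current] >= N_CHOICES_TO_TERMINATE:
                trace.outcome = grid[current]
                return grid[current], trace
            step = 1
            direction = -direction
    raise ConvergenceError("pitch match did not terminate within 200 trials")


def loudness_match(
    listener: VirtualListener, pitch_hz: float, seed: int | None = None
) -> tuple[float, ProcedureTrace]:
    """Ascending 2AFC tinnitus loudness match in 5 dB SL steps.

    Starting from a threshold-level tone vs a 5 dB SL tone at the matched
    pitch, the level advances by 5 dB whenever the listener judges the
    higher tone closer to the tinnitus loudness.  Terminates when the same
    level (threshold included) has been chosen three times; returns it in
    dB SL.  Listeners whose tinnitus has disappeared score 0 by convention.
    """
    trace = ProcedureTrace("loudness_match")
    if not listener.tinnitus_present:
        trace.outcome = 0.0
        return 0.0, trace
    rng = np.random.default_rng(seed)
    counts: dict[float, int] = {}
    level = 0.0
    target = listener.true_loudness_db_sl
    for _ in range(MAX_TRIALS):
        upper = min(level + LEVEL_STEP_DB, MAX_LEVEL_DB)
        pick = _choose(listener, rng, abs(level - target), abs(upper - target))
        chosen = level if pick == 0 else upper
        trace.record(
            {"pitch_hz": round(pitch_hz, 2), "pair_db_sl": [level, upper]}, chosen
        )
        counts[chosen] = counts.get(chosen, 0) + 1
        if counts[chosen] >= N_CHOICES_TO_TERMINATE:
            trace.outcome = chosen
            return chosen, trace
        if chosen == upper and upper < MAX_LEVEL_DB:
            level = upper
    raise ConvergenceError("loudness match did not terminate within 200 trials")


def minimum_masking_level(
    listener: VirtualListener, seed: int | None = None
) -> tuple[float, ProcedureTrace]:
    """Ascending narrowband-noise masking staircase from 0 dB in 5 dB steps.

    Each 5-s step asks whether the tinnitus is still audible; the first
    level at or above the listener's true masking level (perturbed by the
    internal comparison noise) is returned.  Listeners without tinnitus
    score 0 by convention.

    Raises
    ------
    UnmaskableError
        If the tinnitus is still audible at 120 dB.
    """
    trace = ProcedureTrace("minimum_masking_level")
    if not listener.tinnitus_present:
        trace.outcome = 0.0
        return 0.0, trace
    rng = np.random.default_rng(seed)
    level = 0.0
    while level <= MAX_LEVEL_DB:
        threshold = listener.true_masking_db
        if listener.comparison_noise_db > 0:
            threshold = threshold + rng.normal(0.0, listener.comparison_noise_db)
        masked = level >= threshold
        if listener.lapse_prob > 0 and rng.random() < listener.lapse_prob:
            masked = bool(rng.integers(2))
        trace.record({"level_db": level, "step_duration_s": 5.0}, "inaudible" if masked else "audible")
        if masked:
            trace.outcome = level
            return level, trace
        level += LEVEL_STEP_DB
    raise UnmaskableError("tinnitus not masked below 120 dB")


def residual_inhibition_test(
    listener: VirtualListener,
    mml_db: float,
    pitch_hz: float,
    seed: int | None = None,
) -> tuple[RIStatus, ProcedureTrace]:
    """RI probe: 60 s of narrowband noise centered at the tinnitus pitch,
    10 dB above the MML; the post-offset report maps decreased -> positive,
    same/increased -> negative.  A lapse replaces the report with a uniform
    draw over the three verbal responses."""
    rng = np.random.default_rng(seed)
    stimulus = {
        "center_hz": round(pitch_hz, 2),
        "level_db": mml_db + 10.0,
        "duration_s": 60.0,
    }
    if listener.lapse_prob > 0 and rng.random() < listener.lapse_prob:
        response = str(rng.choice(["decreased", "same", "increased"]))
    else:
        response = "decreased" if listener.ri_positive else "same"
    status = RIStatus("positive" if response == "decreased" else "negative")
    trace = ProcedureTrace("residual_inhibition", [(stimulus, response)], status.label)
    return status, trace


_THI_POINTS = {"yes": 4, "sometimes": 2, "no": 0}


def score_thi(responses) -> int:
    """Tinnitus Handicap Inventory total: 25 items scored yes=4 /
    sometimes=2 / no=0; an even integer in [0, 100]."""
    responses = list(responses)
    if len(responses) != 25:
        raise ValueError(f"THI has exactly 25 items, got {len(responses)}")
    try:
        return sum(_THI_POINTS[str(r).strip().lower()] for r in responses)
    except KeyError as e:
        raise ValueError(f"THI responses must be yes/sometimes/no, got {e.args[0]!r}")


def full_assessment(listener: VirtualListener, seed: int | None = None) -> dict:
    """Run the whole battery (pitch -> TLL -> MML -> RI) with substream seeds
    derived from one root seed; returns outcomes and traces."""
    ss = np.random.SeedSequence(seed)
    s_pitch, s_tll, s_mml, s_ri = (int(x) for x in ss.generate_state(4))
    if listener.tinnitus_present:
        pitch, tr_pitch = pitch_match(listener, s_pitch)
    else:
        pitch, tr_pitch = 0.0, ProcedureTrace("pitch_match", [], 0.0)
    tll, tr_tll = loudness_match(listener, pitch, s_tll)
    mml, tr_mml = minimum_masking_level(listener, s_mml)
    if listener.tinnitus_present:
        ri, tr_ri = residual_inhibition_test(listener, mml, pitch, s_ri)
        ri_label = ri.label
    else:
        ri_label, tr_ri = "negative", ProcedureTrace("residual_inhibition", [], "negative")
    return {
        "pitch_hz": pitch,
        "tll_db_sl": tll,
        "mml_db": mml,
        "ri_status": ri_label,
        "traces": [tr_pitch.to_dict(), tr_tll.to_dict(), tr_mml.to_dict(), tr_ri.to_dict()],
    }
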