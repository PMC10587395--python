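"""Experimental design and trial-schedule generation.

The emulated experiment is a two-session slow event-related design.
Session 1 runs pair body (visual half) with voice (auditory half);
session 2 runs pair face with voice.  Each run is split into two
halves of ``trials_per_run_half`` trials: 16 regular trials (4 per
emotion: anger, happy, neutral, fear) plus 2 catch trials, 1 s stimuli,
with an inter-stimulus interval jittered uniformly inside ``isi_range``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ScheduleInfeasibleError

EMOTIONS = ("anger", "happy", "neutral", "fear")
STIMULUS_TYPES = ("face", "body", "voice")

#: columns of a valid event table, in canonical order
EVENT_COLUMNS = (
    "onset",
    "duration",
    "trial_type",
    "stimulus_type",
    "emotion",
    "session",
    "run",
    "run_half",
    "actor",
    "is_catch",
)

# visual stimulus category presented in each session
SESSION_VISUAL_TYPE = {1: "body", 2: "face"}


@dataclass(frozen=True)
class ExperimentDesign:
    """Parameters of the two-session face/body/voice experiment."""

    n_sessions: int = 2
    runs_per_session: int = 6
    volumes_per_run: int = 160
    tr: float = 3.0
    stim_duration: float = 1.0
    isi_range: tuple[float, float] = (10.7, 11.3)
    trials_per_run_half: int = 18
    regular_trials_per_run_half: int = 16
    catch_trials_per_run_half: int = 2
    emotions: tuple[str, ...] = EMOTIONS
    stimulus_types: tuple[str, ...] = STIMULUS_TYPES
    n_actors: int = 4
    lead_in: float = 10.0  # seconds before the first trial of each half

    def __post_init__(self) -> None:
        if self.regular_trials_per_run_half + self.catch_trials_per_run_half != self.trials_per_run_half:
            raise ConfigurationError(
                "regular + catch trials must equal trials_per_run_half"
            )
        if self.regular_trials_per_run_half % len(self.emotions) != 0:
            raise ConfigurationError(
                "regular trials per run half must divide evenly over emotions"
            )
        if self.isi_range[0] > self.isi_range[1] or self.isi_range[0] < 0:
            raise ConfigurationError("invalid isi_range")

    @property
    def n_runs(self) -> int:
        return self.n_sessions * self.runs_per_session

    @property
    def run_duration(self) -> float:
        return self.volumes_per_run * self.tr

    @property
    def half_duration(self) -> float:
        return self.run_duration / 2.0

    @property
    def trials_per_emotion_per_half(self) -> int:
        return self.regular_trials_per_run_half // len(self.emotions)


@dataclass(frozen=True)
class TrialEvent:
    """A single trial of the schedule."""

    onset: float
    duration: float
    stimulus_type: str
    emotion: str
    session: int
    run: int
    run_half: str
    actor: int
    is_catch: bool


def _check_feasible(design: ExperimentDesign) -> None:
    n = design.trials_per_run_half
    required = (
        design.lead_in
        + n * design.stim_duration
        + (n - 1) * design.isi_range[0]
    )
    if required > design.half_duration:
        raise ScheduleInfeasibleError(
            f"cannot place {n} trials of {design.stim_duration}s at minimum ISI "
            f"{design.isi_range[0]}s within a {design.half_duration}s run half"
        )


def build_design(design: ExperimentDesign, seed: int) -> pd.DataFrame:
    """Generate the full two-session event table.

    Emotion order is randomized within each run half, catch trials are
    interleaved at random slots, and the ISI is jittered per gap.  The
    same seed yields a byte-identical table.

    Returns a :class:`pandas.DataFrame` with columns :data:`EVENT_COLUMNS`,
    sorted by run and onset.  The ``run`` index is global (1-based across
    sessions); ``run_half`` is ``"visual"`` or ``"auditory"``.
    """
    _check_feasible(design)
    rng = np.random.default_rng(seed)
    rows: list[TrialEvent] = []
    actor_cycle = 0
    for run in range(1, design.n_runs + 1):
        session = 1 if run <= design.runs_per_session else 2
        visual_type = SESSION_VISUAL_TYPE.get(session, "face")
        half_order = list(rng.permutation(["visual", "auditory"]))
        for half_idx, half in enumerate(half_order):
            half_start = half_idx * design.half_duration
            stim_type = visual_type if half == "visual" else "voice"
            # slot layout: emotions randomized, catch slots interleaved
            emotions = np.repeat(design.emotions, design.trials_per_emotion_per_half)
            emotions = rng.permutation(emotions)
            catch_slots = set(
                rng.choice(
                    design.trials_per_run_half,
                    size=design.catch_trials_per_run_half,
                    replace=False,
                )
            )
            t = half_start + design.lead_in
            emo_iter = iter(emotions)
            for slot in range(design.trials_per_run_half):
                is_catch = slot in catch_slots
                if is_catch:
                    emotion = "n/a"
                    actor = 0
                else:
                    emotion = str(next(emo_iter))
                    actor = actor_cycle % design.n_actors + 1
                    actor_cycle += 1
                rows.append(
                    TrialEvent(
                        onset=round(float(t), 4),
                        duration=design.stim_duration,
                        stimulus_type=stim_type,
                        emotion=emotion,
                        session=session,
                        run=run,
                        run_half=half,
                        actor=actor,
                        is_catch=is_catch,
                    )
                )
                isi = rng.uniform(*design.isi_range)
                t += design.stim_duration + isi
        # trailing trial must stay inside the run
        assert rows[-1].onset + rows[-1].duration <= design.run_duration
    frame = pd.DataFrame(
        {
            "onset": [r.onset for r in rows],
            "duration": [r.duration for r in rows],
            "trial_type": [
                f"{r.stimulus_type}_catch" if r.is_catch else f"{r.stimulus_type}_{r.emotion}"
                for r in rows
            ],
            "stimulus_type": [r.stimulus_type for r in rows],
            "emotion": [r.emotion for r in rows],
            "session": [r.session for r in rows],
            "run": [r.run for r in rows],
            "run_half": [r.run_half for r in rows],
            "actor": [r.actor for r in rows],
            "is_catch": [r.is_catch for r in rows],
        }
    )
    frame = frame.sort_values(["run", "onset"], kind="stable").reset_index(drop=True)
    return frame


def modality_of(run_half: pd.Series | str):
    """Map run-half labels to sensory modality labels (identity mapping,
    kept as an explicit hook: run halves are named after their modality)."""
    return run_half


def validate_events(events: pd.DataFrame) -> None:
    """Check that an event table has the required columns."""
    from .exceptions import ValidationError

    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"event table missing required column(s): {missing}")
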