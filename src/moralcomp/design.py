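"""Trial schedule and token economy of the harm x responsibility interpersonal game.

The game crosses four harm levels (intensity of the electric shock delivered
to the receiver) with four responsibility levels (how many of the four
deciders, including the participant, erred: W wrongdoers, with
responsibility R = 5 - W).  Each of the 16 cells repeats four times, giving
64 experimental ("self-error") trials; 48 filler trials (participant correct)
bring the total to 112, split over 4 sessions of 16 + 12.  On every trial the
decider is endowed 10 tokens (1 token = 0.5 yuan) and allocates an integer
number of them, 0-10, to the receiver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "DesignError",
    "build_schedule",
    "build_schedules",
    "chance_accuracy",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "participant_id",
    "trial_index",
    "session",
    "condition",
    "harm",
    "wrongdoers",
    "responsibility",
    "decision",
]


class DesignError(ValueError):
    """Raised when design constants cannot form a valid schedule."""


@dataclass(frozen=True)
class DesignSpec:
    """Constants of the interpersonal game.

    Defaults reproduce the study design: a 4 x 4 within-subject factorial
    with 4 repeats per cell, 48 fillers, 4 sessions, a 10-token endowment
    worth 0.5 yuan per token, and 11 allocation options (0..10 tokens).
    """

    harm_levels: tuple[int, ...] = (1, 2, 3, 4)
    responsibility_levels: tuple[int, ...] = (1, 2, 3, 4)
    repeats_per_cell: int = 4
    filler_trials: int = 48
    n_sessions: int = 4
    exp_per_session: int = 16
    filler_per_session: int = 12
    endowment_tokens: int = 10
    token_value: float = 0.5
    n_deciders: int = 4

    def __post_init__(self) -> None:
        self.validate()

    # -- derived constants -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.harm_levels) * len(self.responsibility_levels)

    @property
    def n_experimental_trials(self) -> int:
        return self.n_cells * self.repeats_per_cell

    @property
    def total_trials(self) -> int:
        return self.n_experimental_trials + self.filler_trials

    @property
    def decision_options(self) -> np.ndarray:
        """Consecutive integer token amounts 0..endowment."""
        return np.arange(self.endowment_tokens + 1)

    @property
    def max_receiver_income_tokens(self) -> int:
        """Tokens the receiver can collect in one trial if every decider gives all."""
        return self.n_deciders * self.endowment_tokens

    @property
    def max_self_loss_currency(self) -> float:
        """Largest amount (in currency) a decider can forgo on one trial."""
        return self.endowment_tokens * self.token_value

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.exp_per_session * self.n_sessions != self.n_experimental_trials:
            raise DesignError(
                f"{self.n_experimental_trials} experimental trials cannot be "
                f"split into {self.n_sessions} sessions of {self.exp_per_session}"
            )
        if self.filler_per_session * self.n_sessions != self.filler_trials:
            raise DesignError(
                f"{self.filler_trials} filler trials cannot be split into "
                f"{self.n_sessions} sessions of {self.filler_per_session}"
            )
        if self.endowment_tokens < 0 or self.repeats_per_cell < 1:
            raise DesignError("endowment and repeats must be non-negative / positive")


def chance_accuracy(spec: DesignSpec) -> float:
    """Probability of matching a decision by guessing uniformly over the options."""
    n = len(spec.decision_options)
    if n == 0:
        raise DesignError("empty decision option set")
    return 1.0 / n


def _order_without_consecutive_repeats(
    cells: list[tuple[int, int]], rng: np.random.Generator, max_tries: int = 1000
) -> list[tuple[int, int]]:
    """Shuffle so no (harm, responsibility) cell appears on consecutive
    experimental trials; give up after ``max_tries`` shuffles."""
    cells = list(cells)
    for _ in range(max_tries):
        rng.shuffle(cells)
        if all(a != b for a, b in zip(cells, cells[1:])):
            return cells
    return cells


def build_schedule(
    spec: DesignSpec, seed: int | np.random.Generator, participant_id: str = "p001"
) -> pd.DataFrame:
    """Build one participant's trial schedule (decisions left missing).

    Every (harm, responsibility) cell appears ``repeats_per_cell`` times
    across the whole schedule.  When each session holds exactly one full
    factorial (the default design) the cells are balanced within session as
    well.  Fillers are interleaved at random positions; within-session order
    is pseudo-random under ``seed``, with no cell repeating on consecutive
    experimental trials.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    cells = [(h, r) for h in spec.harm_levels for r in spec.responsibility_levels]
    balanced = spec.exp_per_session == spec.n_cells
    if balanced:
        session_cells = [list(cells) for _ in range(spec.n_sessions)]
    else:
        pool = cells * spec.repeats_per_cell
        rng.shuffle(pool)
        session_cells = [
            pool[i * spec.exp_per_session : (i + 1) * spec.exp_per_session]
            for i in range(spec.n_sessions)
        ]

    rows: list[dict] = []
    trial_index = 1
    for s in range(1, spec.n_sessions + 1):
        exp = _order_without_consecutive_repeats(session_cells[s - 1], rng)
        # interleave fillers: choose filler positions among the session's trials
        n_sess = spec.exp_per_session + spec.filler_per_session
        filler_pos = set(
            rng.choice(n_sess, size=spec.filler_per_session, replace=False).tolist()
        )
        it = iter(exp)
        for pos in range(n_sess):
            if pos in filler_pos:
                rows.append(
                    dict(
                        participant_id=participant_id,
                        trial_index=trial_index,
                        session=s,
                        condition="filler",
                        harm=pd.NA,
                        wrongdoers=pd.NA,
                        responsibility=pd.NA,
                        decision=pd.NA,
                    )
                )
            else:
                h, r = next(it)
                rows.append(
                    dict(
                        participant_id=participant_id,
                        trial_index=trial_index,
                        session=s,
                        condition="self_error",
                        harm=h,
                        wrongdoers=5 - r,
                        responsibility=r,
                        decision=pd.NA,
                    )
                )
            trial_index += 1

    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    for col in ("harm", "wrongdoers", "responsibility", "decision"):
        df[col] = df[col].astype("Int64")
    return df


def build_schedules(
    spec: DesignSpec, n_participants: int, seed: int
) -> pd.DataFrame:
    """Schedules for a cohort; one independent pseudo-random order each."""
    streams = np.random.SeedSequence(seed).spawn(n_participants)
    frames = [
        build_schedule(spec, np.random.default_rng(ss), participant_id=f"p{i + 1:03d}")
        for i, ss in enumerate(streams)
    ]
    return pd.concat(frames, ignore_index=True)
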