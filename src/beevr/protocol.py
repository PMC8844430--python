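"""Differential conditioning at the treadmill as a deterministic state machine.

A session is 10 training trials followed by one unreinforced test. During a
training trial the bee faces the two colored cuboids (CS+ rewarded with
sucrose, CS- punished with saline); the trial ends at the first *choice* --
the bee entering a 3 cm radius around a cuboid center while fixating it
frontally -- or at the 60 s timeout (no choice, NC). A choice freezes the
scene for 8 s while the reinforcement is delivered; trials are separated by
a 60 s inter-trial interval. After training, a 60 s test with both cuboids
and no reinforcement determines the bee's category: learners chose the CS+
first in the test, non-learners chose the CS- or nothing. Bees with NC on
five or more training trials are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, SimulationError
from .vr_world import (
    CS_MINUS,
    CS_PLUS,
    EgoMotion,
    StimulusCuboid,
    StimulusView,
    WorldConfig,
    place_stimulus,
)

__all__ = [
    "LEFT",
    "RIGHT",
    "NO_CHOICE",
    "LEARNER",
    "NON_LEARNER",
    "EXCLUDED",
    "ProtocolConfig",
    "TrialRecord",
    "SessionRecord",
    "make_side_schedule",
    "detect_choice",
    "run_trial",
    "run_session",
    "classify_bee",
    "classify_cohort",
    "sessions_to_tables",
]

LEFT = "LEFT"
RIGHT = "RIGHT"
NO_CHOICE = "NC"

LEARNER = "LEARNER"
NON_LEARNER = "NON_LEARNER"
EXCLUDED = "EXCLUDED"

COLORS = ("BLUE", "GREEN")


class Agent(Protocol):
    """Policy interface consumed by :func:`run_session`.

    ``step`` receives the pair of stimulus views in (CS+, CS-) order and a
    random generator and returns the ego-motion for one tick. ``reinforce``
    is called after each reinforced trial that ended in a choice, with the
    chosen role, so learning policies can update.
    """

    def step(self, views: tuple[StimulusView, StimulusView], rng: np.random.Generator) -> EgoMotion: ...

    def reinforce(self, chosen_role: str) -> None: ...


@dataclass(frozen=True)
class ProtocolConfig:
    """All protocol constants; defaults are the study's printed values."""

    n_trials: int = 10
    trial_timeout: float = 60.0
    freeze: float = 8.0
    iti: float = 60.0
    test_duration: float = 60.0
    choice_radius: float = 3.0
    centering_tolerance: float = 5.0
    reward_label: str = "1.5 M sucrose"
    punishment_label: str = "3 M NaCl"
    exclusion_nc_min: int = 5
    choice_anchor: str = "center"  # "center" | "surface"

    def __post_init__(self):
        for name in ("trial_timeout", "freeze", "iti", "test_duration"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.choice_radius <= 0:
            raise ConfigError("choice_radius must be > 0")
        if not (0 < self.centering_tolerance < 90):
            raise ConfigError("centering_tolerance must be in (0, 90)")
        if self.choice_anchor not in ("center", "surface"):
            raise ConfigError(f"unknown choice_anchor {self.choice_anchor!r}")


@dataclass
class TrialRecord:
    """One trial: outcome, latency and the search-phase trajectory.

    The trajectory covers the search phase only (start pose through choice
    or timeout); the 8 s reinforcement freeze, during which the scene is
    locked and the bee's fictive position does not change, is recorded as
    ``freeze_s``. ``latency_s`` is present iff a choice was made.
    """

    index: int
    phase: str  # "train" | "test"
    cs_plus_side: str
    first_choice: str  # CS_PLUS | CS_MINUS | NC
    latency_s: float | None
    freeze_s: float
    reinforcement: str | None
    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    heading_deg: np.ndarray


@dataclass
class SessionRecord:
    """One bee's full session: training trials, the unreinforced test, and
    the constants needed to interpret them."""

    bee_id: str
    cs_plus_color: str
    trials: list[TrialRecord]
    test: TrialRecord
    iti_s: float = 60.0


def make_side_schedule(
    n_trials: int, seed: int | np.random.Generator
) -> list[str]:
    """Pseudo-random CS+ side sequence: balanced, with runs of at most 2.

    The study swapped the rewarded side between left and right pseudo-randomly
    across trials; we pin that down as a balanced sequence (n/2 left, n/2
    right) with no more than two consecutive identical sides, drawn by
    rejection sampling so it is reproducible for a given seed.
    """
    if n_trials % 2 != 0:
        raise ConfigError(f"n_trials must be even for a balanced schedule, got {n_trials}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = np.array([LEFT] * (n_trials // 2) + [RIGHT] * (n_trials // 2))
    while True:
        perm = rng.permutation(base)
        run, ok = 1, True
        for i in range(1, n_trials):
            run = run + 1 if perm[i] == perm[i - 1] else 1
            if run > 2:
                ok = False
                break
        if ok:
            return perm.tolist()


def detect_choice(
    view: StimulusView, config: ProtocolConfig, half_width: float = 0.0
) -> bool:
    """Choice criterion: within the choice radius of the cuboid and fixating it.

    With the default ``center`` anchor the radius is measured to the cuboid
    center; the ``surface`` anchor measures it to the frontal face, i.e.
    adds ``half_width`` to the admissible center distance.
    """
    radius = config.choice_radius
    if config.choice_anchor == "surface":
        radius += half_width
    return (
        view.center_distance <= radius
        and abs(view.azimuth) <= config.centering_tolerance
    )


def _side_azimuths(world: WorldConfig) -> dict[str, float]:
    # CCW-positive azimuths: the larger (more positive) start azimuth is LEFT.
    lo, hi = sorted(world.start_azimuths)
    return {LEFT: hi, RIGHT: lo}


def make_trial_stimuli(
    world: WorldConfig, cs_plus_side: str, cs_plus_color: str
) -> tuple[StimulusCuboid, StimulusCuboid]:
    """Place the CS+ and CS- cuboids for one trial, in (CS+, CS-) order."""
    az = _side_azimuths(world)
    cs_minus_side = RIGHT if cs_plus_side == LEFT else LEFT
    cs_minus_color = COLORS[1] if cs_plus_color == COLORS[0] else COLORS[0]
    plus = place_stimulus(az[cs_plus_side], world.start_distance, color=cs_plus_color, role=CS_PLUS)
    minus = place_stimulus(az[cs_minus_side], world.start_distance, color=cs_minus_color, role=CS_MINUS)
    return plus, minus


def run_trial(
    agent_step: Callable[[tuple[StimulusView, StimulusView], np.random.Generator], EgoMotion],
    stimuli: tuple[StimulusCuboid, StimulusCuboid],
    world: WorldConfig,
    config: ProtocolConfig,
    rng: np.random.Generator,
    *,
    index: int = 1,
    phase: str = "train",
    cs_plus_side: str = LEFT,
    reinforced: bool = True,
    duration: float | None = None,
) -> TrialRecord:
    """Run one trial of the closed loop at the fixed 0.017 s tick.

    Each tick: the views of both stimuli are computed from the current pose,
    the choice criterion is evaluated, and (absent a choice) the agent's
    ego-motion is applied. In a reinforced trial the first choice ends the
    search phase, an 8 s freeze is logged together with the matching
    reinforcement; at timeout the outcome is NC. In an unreinforced (test)
    trial the first choice is recorded but the clock runs to the end and
    nothing is delivered.
    """
    if stimuli[0].role != CS_PLUS or stimuli[1].role != CS_MINUS:
        raise InputError("stimuli must be passed in (CS_PLUS, CS_MINUS) order")
    duration = duration if duration is not None else (
        config.trial_timeout if reinforced else config.test_duration
    )
    n_ticks = int(round(duration / world.tick))
    # Hot loop: the pose update and view computation are inlined (plain
    # floats) for speed; they are exact re-statements of update_pose and
    # stimulus_view, and a regression test holds the two paths together.
    x = y = h = 0.0
    ts = [0.0]
    xs = [0.0]
    ys = [0.0]
    hs = [0.0]
    first_choice = NO_CHOICE
    latency: float | None = None
    (p_cx, p_cy), p_hw = stimuli[0].center, stimuli[0].half_width
    (m_cx, m_cy), m_hw = stimuli[1].center, stimuli[1].half_width
    tol = config.centering_tolerance
    r_plus = config.choice_radius + (p_hw if config.choice_anchor == "surface" else 0.0)
    r_minus = config.choice_radius + (m_hw if config.choice_anchor == "surface" else 0.0)
    tick = world.tick
    hypot, atan2, degrees, radians, sin, cos, fmod = (
        math.hypot, math.atan2, math.degrees, math.radians, math.sin, math.cos, math.fmod,
    )

    for k in range(1, n_ticks + 1):
        dx = p_cx - x
        dy = p_cy - y
        d0 = hypot(dx, dy)
        if d0 < 1e-9:
            raise SimulationError("bee reached a stimulus center exactly")
        a0 = fmod(degrees(atan2(-dx, dy)) - h, 360.0)
        if a0 > 180.0:
            a0 -= 360.0
        elif a0 <= -180.0:
            a0 += 360.0
        dx = m_cx - x
        dy = m_cy - y
        d1 = hypot(dx, dy)
        if d1 < 1e-9:
            raise SimulationError("bee reached a stimulus center exactly")
        a1 = fmod(degrees(atan2(-dx, dy)) - h, 360.0)
        if a1 > 180.0:
            a1 -= 360.0
        elif a1 <= -180.0:
            a1 += 360.0
        views = (
            StimulusView(a0, d0, degrees(2.0 * atan2(p_hw, d0))),
            StimulusView(a1, d1, degrees(2.0 * atan2(m_hw, d1))),
        )
        if first_choice == NO_CHOICE:
            if d0 <= r_plus and -tol <= a0 <= tol:
                first_choice = CS_PLUS
            elif d1 <= r_minus and -tol <= a1 <= tol:
                first_choice = CS_MINUS
            if first_choice != NO_CHOICE:
                latency = ts[-1]
                if reinforced:
                    break
        motion = agent_step(views, rng)
        fwd = motion.forward
        lat = motion.lateral
        yaw = motion.yaw
        if not (math.isfinite(fwd) and math.isfinite(lat) and math.isfinite(yaw)):
            raise SimulationError(f"agent returned non-finite motion at t={k * tick:.3f}")
        theta = radians(h)
        sin_t = sin(theta)
        cos_t = cos(theta)
        x += lat * cos_t - fwd * sin_t
        y += lat * sin_t + fwd * cos_t
        h = fmod(h + yaw, 360.0)
        if h > 180.0:
            h -= 360.0
        elif h <= -180.0:
            h += 360.0
        ts.append(k * tick)
        xs.append(x)
        ys.append(y)
        hs.append(h)

    chose = first_choice != NO_CHOICE
    reinforcement = None
    freeze_s = 0.0
    if chose and reinforced:
        freeze_s = config.freeze
        reinforcement = (
            config.reward_label if first_choice == CS_PLUS else config.punishment_label
        )
    return TrialRecord(
        index=index,
        phase=phase,
        cs_plus_side=cs_plus_side,
        first_choice=first_choice,
        latency_s=latency,
        freeze_s=freeze_s,
        reinforcement=reinforcement,
        t_s=np.asarray(ts),
        x_cm=np.asarray(xs),
        y_cm=np.asarray(ys),
        heading_deg=np.asarray(hs),
    )


def run_session(
    agent: Agent,
    world: WorldConfig,
    config: ProtocolConfig,
    seed: int,
    *,
    bee_id: str = "bee-0",
    cs_plus_color: str | None = None,
) -> SessionRecord:
    """Run a full session: n training trials with the side schedule, then the test.

    The CS+ color is assigned at random (or fixed by the caller); the CS+
    side follows the balanced pseudo-random schedule. After every reinforced
    choice the agent receives the chosen role as feedback so that learning
    policies can update. The test trial delivers no reinforcement.
    """
    rng = np.random.default_rng(seed)
    if cs_plus_color is None:
        cs_plus_color = str(rng.choice(COLORS))
    schedule = make_side_schedule(config.n_trials, rng)
    trials: list[TrialRecord] = []
    for i, side in enumerate(schedule, start=1):
        stimuli = make_trial_stimuli(world, side, cs_plus_color)
        rec = run_trial(
            agent.step, stimuli, world, config, rng,
            index=i, phase="train", cs_plus_side=side, reinforced=True,
        )
        trials.append(rec)
        if rec.first_choice != NO_CHOICE:
            agent.reinforce(rec.first_choice)
    test_side = schedule[-1]  # same arena layout as the last trial
    stimuli = make_trial_stimuli(world, test_side, cs_plus_color)
    test = run_trial(
        agent.step, stimuli, world, config, rng,
        index=config.n_trials + 1, phase="test", cs_plus_side=test_side,
        reinforced=False, duration=config.test_duration,
    )
    return SessionRecord(
        bee_id=bee_id, cs_plus_color=cs_plus_color, trials=trials, test=test,
        iti_s=config.iti,
    )


def classify_bee(session: SessionRecord, config: ProtocolConfig) -> str:
    """Categorize a session: EXCLUDED, LEARNER or NON_LEARNER.

    A bee unable to choose on ``exclusion_nc_min`` or more training trials is
    excluded from analysis. Otherwise it is a learner iff its first test
    choice was the CS+; bees that chose the CS- or made no test choice are
    non-learners.
    """
    if len(session.trials) != config.n_trials or session.test is None:
        raise InputError(
            f"incomplete session for {session.bee_id}: "
            f"{len(session.trials)} trials, test={'present' if session.test else 'missing'}"
        )
    nc = sum(1 for t in session.trials if t.first_choice == NO_CHOICE)
    if nc >= config.exclusion_nc_min:
        return EXCLUDED
    return LEARNER if session.test.first_choice == CS_PLUS else NON_LEARNER


def classify_cohort(
    sessions: Sequence[SessionRecord], config: ProtocolConfig
) -> pd.DataFrame:
    """Categorize every session; returns columns bee_id, category."""
    return pd.DataFrame(
        {
            "bee_id": [s.bee_id for s in sessions],
            "category": [classify_bee(s, config) for s in sessions],
        }
    )


def sessions_to_tables(
    sessions: Sequence[SessionRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten sessions into the two tabular interchange formats.

    Returns ``(trials, trajectories)``: per-trial outcomes (one row per
    training trial and test, with the ITI that followed training trials) and
    the tick-resolution search-phase trajectories.
    """
    trial_rows = []
    traj_frames = []
    for s in sessions:
        for rec in [*s.trials, s.test]:
            trial_rows.append(
                {
                    "bee_id": s.bee_id,
                    "trial": rec.index,
                    "phase": rec.phase,
                    "cs_plus_side": rec.cs_plus_side,
                    "first_choice": rec.first_choice,
                    "latency_s": np.nan if rec.latency_s is None else rec.latency_s,
                    "freeze_s": rec.freeze_s,
                    "iti_s": s.iti_s if rec.phase == "train" else np.nan,
                }
            )
            traj_frames.append(
                pd.DataFrame(
                    {
                        "bee_id": s.bee_id,
                        "trial": rec.index,
                        "phase": rec.phase,
                        "t_s": rec.t_s,
                        "x_cm": rec.x_cm,
                        "y_cm": rec.y_cm,
                        "heading_deg": rec.heading_deg,
                    }
                )
            )
    return pd.DataFrame(trial_rows), pd.concat(traj_frames, ignore_index=True)
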