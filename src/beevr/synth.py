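"""Synthetic bees and synthetic Cq plates with exported ground truth.

The walking agent is a salience-weighted attraction walk: each tick it
steps forward at constant speed and turns toward the stimuli at a rate

    turn = gain * sum_s u_s * sin(azimuth_s) / sum_s u_s  +  noise,

where the drive ``u_s`` of stimulus s is its associative weight multiplied
by an exponential of its subtended visual angle. The looming term makes the
closer (larger-looking) cuboid dominate steering, so an initially unbiased
agent commits to one of the two stimuli instead of stalling between them;
the associative weights bias which one. Reinforcement feedback moves the
weights: a rewarded CS+ choice increments the CS+ weight by the learning
rate, a punished CS- choice decrements the CS- weight. With learning rate 0
the policy is statistically side- and stimulus-symmetric. The agent is a
test harness for the analysis chain, not a model of bee cognition.

The Cq simulator draws, per bee x gene x region, a triplicate
``baseline + group effect + bee-level N(0, bee_sd) + replicate N(0, tech_sd)``
with occasional outlier replicates shifted upward, and exports the injected
truth (the fold change implied by each group effect at the gene's primer
efficiency) for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .protocol import (
    LEARNER,
    NON_LEARNER,
    ProtocolConfig,
    SessionRecord,
    run_session,
)
from .qpcr import (
    REGIONS,
    TABLE_PRIMERS,
    TARGET_GENES,
    compare_all,
    normalized_expression_table,
)
from .vr_world import CS_MINUS, CS_PLUS, EgoMotion, StimulusView, WorldConfig

__all__ = [
    "AgentParams",
    "WalkingAgent",
    "LEARNER_AGENT",
    "NONLEARNER_AGENT",
    "agent_step",
    "simulate_behavior_cohort",
    "CqSimDesign",
    "simulate_cq_dataset",
    "recovery_report",
]


@dataclass(frozen=True)
class AgentParams:
    """Walking-agent parameters.

    base_speed
        Forward walking speed, cm/s.
    heading_noise
        SD of the per-tick heading perturbation, degrees.
    attraction_gain
        Maximum turning rate toward the salience-weighted stimulus
        direction, degrees/s.
    learning_rate
        Associative weight increment per reinforcement, in [0, 1]; 0 gives
        a non-learning, stimulus-symmetric policy.
    initial_bias
        Starting associative weight of both stimuli.
    salience_sharpness
        Exponential gain (per degree of subtense) of the looming term.
    """

    base_speed: float = 2.5
    heading_noise: float = 2.5
    attraction_gain: float = 90.0
    learning_rate: float = 0.0
    initial_bias: float = 0.5
    salience_sharpness: float = 0.15
    weight_max: float = 1.0
    weight_min: float = 0.05

    def __post_init__(self):
        if self.base_speed <= 0:
            raise InputError("base_speed must be > 0")
        if not (0 <= self.learning_rate <= 1):
            raise InputError("learning_rate must be in [0, 1]")
        if self.heading_noise < 0:
            raise InputError("heading_noise must be >= 0")


#: study-condition agents: learners update weights on reinforcement, non-learners do not
LEARNER_AGENT = AgentParams(learning_rate=0.25)
NONLEARNER_AGENT = AgentParams(learning_rate=0.0)


def agent_step(
    params: AgentParams,
    weights: tuple[float, float],
    views: tuple[StimulusView, StimulusView],
    rng: np.random.Generator,
    tick: float,
) -> EgoMotion:
    """One tick of the salience-weighted attraction walk.

    ``weights`` are the (CS+, CS-) associative weights matching the view
    order. Pure function of its inputs apart from the noise draw.
    """
    beta = params.salience_sharpness
    u0 = weights[0] * math.exp(beta * views[0].subtended_angle)
    u1 = weights[1] * math.exp(beta * views[1].subtended_angle)
    total = u0 + u1
    if total > 0:
        turn_rate = params.attraction_gain * (
            u0 * math.sin(math.radians(views[0].azimuth))
            + u1 * math.sin(math.radians(views[1].azimuth))
        ) / total
    else:
        turn_rate = 0.0
    yaw = turn_rate * tick
    if params.heading_noise > 0:
        yaw += rng.normal(0.0, params.heading_noise)
    return EgoMotion(forward=params.base_speed * tick, lateral=0.0, yaw=yaw)


class WalkingAgent:
    """Stateful policy wrapping :func:`agent_step` with learnable weights."""

    def __init__(self, params: AgentParams, tick: float = 0.017):
        self.params = params
        self.tick = tick
        self.w_plus = params.initial_bias
        self.w_minus = params.initial_bias

    def step(
        self, views: tuple[StimulusView, StimulusView], rng: np.random.Generator
    ) -> EgoMotion:
        return agent_step(self.params, (self.w_plus, self.w_minus), views, rng, self.tick)

    def reinforce(self, chosen_role: str) -> None:
        lr = self.params.learning_rate
        if lr == 0:
            return
        if chosen_role == CS_PLUS:
            self.w_plus = min(self.params.weight_max, self.w_plus + lr)
        elif chosen_role == CS_MINUS:
            self.w_minus = max(self.params.weight_min, self.w_minus - lr)


def simulate_behavior_cohort(
    n_bees: int,
    learner_fraction: float = 0.5,
    *,
    learner_params: AgentParams = LEARNER_AGENT,
    nonlearner_params: AgentParams = NONLEARNER_AGENT,
    world: WorldConfig | None = None,
    protocol: ProtocolConfig | None = None,
    seed: int = 0,
) -> tuple[list[SessionRecord], pd.DataFrame]:
    """Simulate a cohort of full conditioning sessions.

    A fraction of the bees run with the learner parameterization (weights
    updated on reinforcement), the rest with the non-learner one; the
    assignment is shuffled. Returns the sessions and a ground-truth table
    (bee_id, simulated_learner) for recovery checks. Bit-identical for a
    given seed.
    """
    if n_bees < 1:
        raise InputError("n_bees must be >= 1")
    if not (0 <= learner_fraction <= 1):
        raise InputError("learner_fraction must be in [0, 1]")
    world = world if world is not None else WorldConfig()
    protocol = protocol if protocol is not None else ProtocolConfig()
    rng = np.random.default_rng(seed)
    n_learners = int(round(learner_fraction * n_bees))
    is_learner = np.array([True] * n_learners + [False] * (n_bees - n_learners))
    rng.shuffle(is_learner)
    bee_seeds = rng.integers(0, 2**31 - 1, size=n_bees)
    sessions = []
    for i in range(n_bees):
        params = learner_params if is_learner[i] else nonlearner_params
        agent = WalkingAgent(params, tick=world.tick)
        sessions.append(
            run_session(
                agent, world, protocol, int(bee_seeds[i]),
                bee_id=f"bee-{i + 1:03d}",
            )
        )
    truth = pd.DataFrame(
        {
            "bee_id": [s.bee_id for s in sessions],
            "simulated_learner": is_learner,
        }
    )
    return sessions, truth


def _default_baselines() -> dict[tuple[str, str], float]:
    """Plausible mean Cq per (gene, region): reference genes abundant (~20
    cycles), immediate-early genes sparser (26-30), small region offsets."""
    gene_base = {"kakusei": 28.0, "Hr38": 30.0, "Egr1": 26.0, "Ef1a": 20.0, "Actin": 19.0}
    region_off = {"OL": 0.5, "MB": 0.0, "CB": -0.5}
    return {
        (g, r): gene_base[g] + region_off[r] for g in gene_base for r in region_off
    }


@dataclass(frozen=True)
class CqSimDesign:
    """Design of a synthetic qPCR experiment.

    ``group_effect_cq`` maps (gene, region, group) to a Cq shift in cycles;
    a negative shift means earlier amplification, i.e. upregulation by a
    factor (1+E)^(-shift). The default injects the study design's headline
    effect: Egr1 shifted -1 cycle in mushroom-body samples of learners.
    Bee-level biological noise is normal on Cq (lognormal on expression).
    """

    baseline_cq: dict[tuple[str, str], float] = field(default_factory=_default_baselines)
    group_effect_cq: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: {("Egr1", "MB", LEARNER): -1.0}
    )
    bee_sd: float = 0.5
    tech_sd: float = 0.1
    outlier_prob: float = 0.02
    outlier_shift: float = 2.0
    group_sizes: tuple[int, int] = (17, 14)
    genes: tuple[str, ...] = ("kakusei", "Hr38", "Egr1", "Ef1a", "Actin")
    regions: tuple[str, ...] = REGIONS
    seed: int = 0

    def __post_init__(self):
        if self.tech_sd < 0 or self.bee_sd < 0:
            raise InputError("noise SDs must be >= 0")
        if not (0 <= self.outlier_prob <= 1):
            raise InputError("outlier_prob must be in [0, 1]")


def simulate_cq_dataset(
    design: CqSimDesign, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a long-format Cq table from a design, plus its ground truth.

    Returns ``(cq, truth)``. ``cq`` has one row per technical replicate with
    an ``is_outlier`` column marking injected outliers (analysis code must
    ignore it). ``truth`` lists, per gene x region, the injected
    learner-vs-non-learner Cq effect and the fold change it implies at the
    gene's primer efficiency.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n_l, n_n = design.group_sizes
    bees = [(f"L{i + 1:02d}", LEARNER) for i in range(n_l)] + [
        (f"N{i + 1:02d}", NON_LEARNER) for i in range(n_n)
    ]
    rows = []
    for gene in design.genes:
        for region in design.regions:
            base = design.baseline_cq[(gene, region)]
            for bee_id, group in bees:
                mu = base + design.group_effect_cq.get((gene, region, group), 0.0)
                level = mu + rng.normal(0.0, design.bee_sd)
                reps = level + rng.normal(0.0, design.tech_sd, size=3)
                outliers = rng.random(3) < design.outlier_prob
                reps = reps + outliers * design.outlier_shift
                for j in range(3):
                    rows.append(
                        {
                            "bee_id": bee_id,
                            "group": group,
                            "region": region,
                            "gene": gene,
                            "replicate": j + 1,
                            "cq": reps[j],
                            "is_outlier": bool(outliers[j]),
                        }
                    )
    cq = pd.DataFrame(rows)
    truth_rows = []
    for gene in design.genes:
        eff = TABLE_PRIMERS[gene].efficiency
        for region in design.regions:
            effect = design.group_effect_cq.get(
                (gene, region, LEARNER), 0.0
            ) - design.group_effect_cq.get((gene, region, NON_LEARNER), 0.0)
            truth_rows.append(
                {
                    "gene": gene,
                    "region": region,
                    "effect_cq": effect,
                    "efficiency": eff,
                    "true_fold_change": (1.0 + eff) ** (-effect),
                }
            )
    return cq, pd.DataFrame(truth_rows)


def recovery_report(
    design: CqSimDesign,
    n_replicates: int,
    seed: int = 0,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Monte-Carlo recovery of the injected fold changes through the full
    quantification pipeline.

    Per gene x region: bias and RMSE of the estimated log fold change
    (log of the ratio of group means of normalized expression) against the
    injected truth, and the rejection rate of the group comparison at
    ``alpha``. Under a null design the rejection rate is the empirical
    type-I error.
    """
    if n_replicates < 1:
        raise InputError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    _, truth = simulate_cq_dataset(design, seed=int(rep_seeds[0]))
    truth = truth.set_index(["gene", "region"])
    acc: dict[tuple[str, str], dict[str, list[float]]] = {}
    for s in rep_seeds:
        cq, _ = simulate_cq_dataset(design, seed=int(s))
        expr, _ = normalized_expression_table(cq.drop(columns=["is_outlier"]))
        cmp = compare_all(expr)
        for row in cmp.itertuples():
            key = (row.gene, row.region)
            slot = acc.setdefault(key, {"lfc": [], "reject": []})
            slot["lfc"].append(math.log(row.fold_change))
            slot["reject"].append(float(row.p_value < alpha))
    rows = []
    for (gene, region), slot in sorted(acc.items()):
        lfc = np.asarray(slot["lfc"])
        true_lfc = math.log(truth.loc[(gene, region), "true_fold_change"])
        rows.append(
            {
                "gene": gene,
                "region": region,
                "true_log_fold_change": true_lfc,
                "mean_log_fold_change": lfc.mean(),
                "bias": lfc.mean() - true_lfc,
                "rmse": float(np.sqrt(np.mean((lfc - true_lfc) ** 2))),
                "rejection_rate": float(np.mean(slot["reject"])),
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows)
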