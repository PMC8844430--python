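"""Trajectory metrics, choice-proportion learning curves and group statistics.

Motor metrics are computed per trial on the search-phase trajectory: total
distance walked, walking speed (distance over active search time, the
reinforcement freeze excluded) and tortuosity, the ratio of the distance
walked to the straight-line distance between the first and last points of
the trajectory. A ratio of 1 is a perfectly straight path; the ratio is
undefined (NaN) when the net displacement is below 0.1 cm, e.g. for closed
loops.

Learning curves are the per-trial percentages of bees whose first choice was
the CS+, the CS-, or no choice, with Wilson 95% confidence intervals. Two
inferential routes are provided: a self-contained permutation test on the
trial-slope of the choice proportions, and mixed models (binomial GLMM for
choices, LMMs for the motor variables, bee as random intercept) delegated to
statsmodels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import InputError
from .protocol import NO_CHOICE, ProtocolConfig, TrialRecord
from .vr_world import CS_MINUS, CS_PLUS

__all__ = [
    "MotorSummary",
    "tortuosity",
    "motor_summary",
    "motor_summary_table",
    "choice_proportions",
    "interaction_permutation_test",
    "fit_mixed_models",
]

#: net displacements below this (cm) make the tortuosity denominator unreliable
TORTUOSITY_EPS_CM = 0.1


@dataclass(frozen=True)
class MotorSummary:
    """Per-trial motor metrics; ``tortuosity`` is NaN when undefined."""

    distance: float
    speed: float
    tortuosity: float


def _path_length(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.hypot(np.diff(x), np.diff(y)).sum())


def tortuosity(x, y, eps: float = TORTUOSITY_EPS_CM) -> float:
    """Path length divided by net start-to-end displacement.

    Returns NaN (undefined) instead of raising when the net displacement is
    below ``eps`` cm, as for a closed loop.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.shape != y.shape:
        raise InputError("tortuosity needs >= 2 matching samples")
    net = math.hypot(x[-1] - x[0], y[-1] - y[0])
    if net < eps:
        return float("nan")
    return _path_length(x, y) / net


def motor_summary(trial: TrialRecord) -> MotorSummary:
    """Distance (cm), speed (cm/s) and tortuosity of one trial's search phase.

    The speed denominator is the active search time: the choice latency when
    a choice was made, else the full trajectory duration. The freeze never
    enters (the trajectory covers the search phase only).
    """
    if trial.t_s.size < 2:
        raise InputError(f"trial {trial.index} has no usable trajectory")
    dist = _path_length(trial.x_cm, trial.y_cm)
    duration = trial.latency_s if trial.latency_s is not None else float(trial.t_s[-1])
    if duration <= 0:
        raise InputError(f"trial {trial.index} has non-positive search duration")
    return MotorSummary(
        distance=dist,
        speed=dist / duration,
        tortuosity=tortuosity(trial.x_cm, trial.y_cm),
    )


def motor_summary_table(trajectories: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Motor metrics for every (bee, trial) from the tabular interchange format.

    For test-phase rows of unreinforced trials the full trajectory is the
    search phase. Undefined tortuosity is NaN in the output.
    """
    rows = []
    lat = trials.set_index(["bee_id", "trial"])["latency_s"]
    for (bee, trial, phase), g in trajectories.groupby(["bee_id", "trial", "phase"], sort=True):
        x = g["x_cm"].to_numpy()
        y = g["y_cm"].to_numpy()
        t = g["t_s"].to_numpy()
        if t.size < 2:
            continue
        dist = _path_length(x, y)
        latency = lat.get((bee, trial), np.nan)
        duration = latency if (phase == "train" and np.isfinite(latency)) else float(t[-1])
        rows.append(
            {
                "bee_id": bee,
                "trial": trial,
                "phase": phase,
                "distance_cm": dist,
                "speed_cm_s": dist / duration if duration > 0 else np.nan,
                "tortuosity": tortuosity(x, y),
            }
        )
    return pd.DataFrame(rows)


def choice_proportions(trials: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-trial (and test) proportions of CS+/CS-/NC first choices with
    Wilson score confidence intervals.

    Input is the trials table restricted to the bees of interest (e.g. one
    category). Proportions within a trial sum to 1.
    """
    if trials.empty:
        raise InputError("choice_proportions: empty group")
    rows = []
    for (phase, trial), g in trials.groupby(["phase", "trial"], sort=True):
        n = len(g)
        row = {"phase": phase, "trial": trial, "n": n}
        for label, key in ((CS_PLUS, "cs_plus"), (CS_MINUS, "cs_minus"), (NO_CHOICE, "nc")):
            k = int((g["first_choice"] == label).sum())
            lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
            row[f"p_{key}"] = k / n
            row[f"ci_low_{key}"] = float(lo)
            row[f"ci_high_{key}"] = float(hi)
        rows.append(row)
    return pd.DataFrame(rows)


def _choice_matrix(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Encode training choices as a (bees x trials) sign matrix.

    +1 = CS+, -1 = CS-, 0 = NC; columns ordered by trial index. Returns the
    matrix and the centered trial covariate used for slopes.
    """
    train = trials[trials["phase"] == "train"]
    pivot = train.pivot_table(
        index="bee_id", columns="trial", values="first_choice", aggfunc="first"
    ).sort_index(axis=1)
    m = np.zeros(pivot.shape)
    m[(pivot == CS_PLUS).to_numpy()] = 1.0
    m[(pivot == CS_MINUS).to_numpy()] = -1.0
    k = pivot.shape[1]
    c = np.arange(1, k + 1, dtype=float)
    c -= c.mean()
    c /= (c**2).sum()  # OLS slope weights
    return m, c


def interaction_permutation_test(
    trials: pd.DataFrame,
    factor: str = "cs",
    *,
    categories: pd.DataFrame | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for a stimulus-by-trial (or condition-by-trial)
    interaction in the first-choice curves.

    ``factor="cs"``: statistic = slope over trials of (CS+ proportion minus
    CS- proportion); the null swaps the CS+/CS- labels independently within
    each bee (a sign flip of its choice-sign row), which is exchangeable
    when the bee has no CS preference dynamics. One-sided: large positive
    slopes (CS+ rising relative to CS-) are evidence of learning.

    ``factor="condition"``: statistic = difference between two categories in
    the slope of the CS+ proportion; the null permutes category labels
    across bees (``categories`` must provide bee_id -> category with exactly
    two levels).

    ``p = (1 + #{perm >= obs}) / (1 + n_perm)``; degenerate inputs (all
    outcomes identical) give p = 1.
    """
    if n_perm < 99:
        raise InputError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    m, c = _choice_matrix(trials)
    n_bees = m.shape[0]
    if factor == "cs":
        v = m @ c  # per-bee slope of (CS+ minus CS-) indicator
        obs = v.mean()
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_bees))
        stats = (signs @ v) / n_bees
    elif factor == "condition":
        if categories is None:
            raise InputError("factor='condition' requires a categories table")
        cats = categories.set_index("bee_id")["category"]
        train = trials[trials["phase"] == "train"]
        pivot = train.pivot_table(
            index="bee_id", columns="trial", values="first_choice", aggfunc="first"
        ).sort_index(axis=1)
        labels = cats.reindex(pivot.index)
        levels = sorted(labels.dropna().unique())
        if len(levels) != 2:
            raise InputError(f"condition factor needs exactly 2 categories, got {levels}")
        plus = (pivot == CS_PLUS).to_numpy(dtype=float)
        u = plus @ c  # per-bee slope of the CS+ indicator
        is_a = (labels == levels[0]).to_numpy()
        obs = u[is_a].mean() - u[~is_a].mean()
        stats = np.empty(n_perm)
        lab = is_a.copy()
        for i in range(n_perm):
            rng.shuffle(lab)
            stats[i] = u[lab].mean() - u[~lab].mean()
    else:
        raise InputError(f"unknown factor {factor!r}")
    return float((1 + np.sum(stats >= obs - 1e-12)) / (1 + n_perm))


def fit_mixed_models(
    trials: pd.DataFrame,
    motor: pd.DataFrame,
    categories: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Mixed-model summaries for choices and motor variables.

    Choice model: binomial mixed model of "first choice was CS+" (NC trials
    excluded) on trial number with a bee random intercept, fit by
    statsmodels' variational Bayes routine. Motor models: linear mixed
    models of distance/speed/tortuosity on condition * trial with a bee
    random intercept. Every table carries columns term, estimate,
    statistic, p and a ``converged`` flag; non-convergence is flagged, not
    raised.
    """
    from scipy import stats as sps
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
    from statsmodels.regression.mixed_linear_model import MixedLM

    out: dict[str, pd.DataFrame] = {}

    train = trials[(trials["phase"] == "train") & (trials["first_choice"] != NO_CHOICE)].copy()
    train["chose_plus"] = (train["first_choice"] == CS_PLUS).astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = BinomialBayesMixedGLM.from_formula(
                "chose_plus ~ trial", {"bee": "0 + C(bee_id)"}, train
            )
            fit = model.fit_vb()
        names = list(fit.model.exog_names)
        means = np.asarray(fit.fe_mean)
        sds = np.asarray(fit.fe_sd)
        z = means / sds
        out["choice_glmm"] = pd.DataFrame(
            {
                "term": names,
                "estimate": means,
                "statistic": z,
                "p": 2 * sps.norm.sf(np.abs(z)),
                "converged": True,
            }
        )
    except Exception as exc:  # noqa: BLE001 - flagged, not raised, per contract
        out["choice_glmm"] = pd.DataFrame(
            [{"term": "(failed)", "estimate": np.nan, "statistic": np.nan, "p": np.nan,
              "converged": False, "message": str(exc)}]
        )

    merged = motor[motor["phase"] == "train"].merge(categories, on="bee_id")
    for metric in ("distance_cm", "speed_cm_s", "tortuosity"):
        sub = merged.dropna(subset=[metric])
        key = f"{metric.split('_')[0]}_lmm" if metric != "tortuosity" else "tortuosity_lmm"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM.from_formula(
                    f"{metric} ~ C(category) * trial", groups="bee_id", data=sub
                )
                fit = model.fit(reml=True)
            rows = []
            for term in fit.fe_params.index:
                est = fit.fe_params[term]
                se = fit.bse_fe[term]
                z = est / se if se > 0 else np.nan
                rows.append(
                    {
                        "term": term,
                        "estimate": est,
                        "statistic": z,
                        "p": 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                        "converged": bool(fit.converged),
                    }
                )
            rows.append(
                {
                    "term": "random_intercept_var",
                    "estimate": float(np.asarray(fit.cov_re).ravel()[0]),
                    "statistic": np.nan,
                    "p": np.nan,
                    "converged": bool(fit.converged),
                }
            )
            out[key] = pd.DataFrame(rows)
        except Exception as exc:  # noqa: BLE001
            out[key] = pd.DataFrame(
                [{"term": "(failed)", "estimate": np.nan, "statistic": np.nan, "p": np.nan,
                  "converged": False, "message": str(exc)}]
            )
    return out
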