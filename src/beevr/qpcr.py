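"""Efficiency-corrected relative quantification of RT-qPCR Cq data.

The pipeline mirrors standard single-plate relative quantification:

1. *Triplicate QC* — each sample is run in technical triplicate; if the
   triplicate SD exceeds 0.3 cycles the replicate farthest from the
   triplicate mean is dropped, and if the remaining pair still exceeds the
   threshold the sample is discarded.
2. *Relative quantity* — per gene x brain-region batch, each sample's mean
   Cq is referenced to the batch's highest mean Cq:
   ``Qr = (1 + E) ** (max_Cq - mean_Cq)``, with E the primer's amplification
   efficiency (1.0 = perfect doubling per cycle). The sample with the
   highest mean Cq therefore has Qr = 1.
3. *Normalization* — each sample's target-gene Qr is divided by a
   normalization factor, the geometric mean of the reference-gene Qr values
   of the same sample. Which reference genes are used is a per-region
   policy: both Ef1a and Actin for the mushroom-body calyces (MB) and
   central brain (CB), Actin alone for the optic lobes (OL), where Ef1a was
   not stable between groups.
4. *Group comparison* — normalized expression is compared between learners
   and non-learners per gene and region with a pooled-variance two-sample
   t-test (df = n1 + n2 - 2), two-sided, alpha 0.05, no multiple-testing
   correction and no cross-region or cross-gene comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, OrderingError

__all__ = [
    "PrimerSpec",
    "QCResult",
    "GroupComparison",
    "TABLE_PRIMERS",
    "DEFAULT_POLICY",
    "REFERENCE_GENES",
    "TARGET_GENES",
    "triplicate_qc",
    "relative_quantity",
    "normalization_factor",
    "normalized_expression_table",
    "reference_stability_test",
    "compare_groups",
    "compare_all",
    "fold_change_estimates",
]

REGIONS = ("OL", "MB", "CB")
GROUPS = ("LEARNER", "NON_LEARNER")
REFERENCE_GENES = frozenset({"Ef1a", "Actin"})
TARGET_GENES = ("kakusei", "Hr38", "Egr1")

QC_PASS = "PASS"
QC_OUTLIER_DROPPED = "OUTLIER_DROPPED"
QC_DISCARDED = "DISCARDED"

#: primer efficiencies outside this band are flagged (assay range was 95-110%)
EFFICIENCY_WARN_BAND = (0.9, 1.2)


@dataclass(frozen=True)
class PrimerSpec:
    """Primer-assay constants: efficiency as a fraction (1.06 = 106%),
    amplicon length in bp and the standard-curve R^2."""

    gene: str
    efficiency: float
    amplicon_length: int
    r_squared: float

    def __post_init__(self):
        if self.efficiency <= 0:
            raise InputError(f"{self.gene}: efficiency must be > 0")
        if self.amplicon_length <= 0:
            raise InputError(f"{self.gene}: amplicon length must be > 0")
        lo, hi = EFFICIENCY_WARN_BAND
        if not (lo <= self.efficiency <= hi):
            warnings.warn(
                f"{self.gene}: efficiency {self.efficiency:.3f} outside the "
                f"[{lo}, {hi}] assay band",
                stacklevel=2,
            )


#: assay constants for the three immediate-early genes and two reference genes
TABLE_PRIMERS: dict[str, PrimerSpec] = {
    "kakusei": PrimerSpec("kakusei", 0.964, 149, 0.991),
    "Hr38": PrimerSpec("Hr38", 1.06, 118, 0.995),
    "Egr1": PrimerSpec("Egr1", 1.09, 138, 0.991),
    "Ef1a": PrimerSpec("Ef1a", 1.06, 148, 0.993),
    "Actin": PrimerSpec("Actin", 1.10, 156, 0.995),
}

#: per-region reference genes used for normalization
DEFAULT_POLICY: dict[str, frozenset[str]] = {
    "MB": frozenset({"Ef1a", "Actin"}),
    "CB": frozenset({"Ef1a", "Actin"}),
    "OL": frozenset({"Actin"}),
}


@dataclass(frozen=True)
class QCResult:
    """Outcome of triplicate QC: the retained Cq values (empty iff discarded)
    and the status."""

    retained: tuple[float, ...]
    status: str


@dataclass(frozen=True)
class GroupComparison:
    """Pooled two-sample t comparison of normalized expression between groups."""

    t_statistic: float
    df: int
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    gene: str | None = None
    region: str | None = None
    infinite_t: bool = False


def _sample_sd(values) -> float:
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def triplicate_qc(cq_values, sd_threshold: float = 0.3) -> QCResult:
    """Apply the triplicate variability rule to one sample.

    Sample SD (n-1 denominator) at or below the threshold passes all three
    values. Otherwise the replicate farthest from the triplicate mean is
    dropped (exact distance ties broken by dropping the larger Cq) and the
    remaining pair is re-tested; a pair still above the threshold discards
    the sample.
    """
    values = [float(v) for v in cq_values]
    if len(values) != 3:
        raise InputError(f"triplicate QC needs exactly 3 values, got {len(values)}")
    if not all(math.isfinite(v) for v in values):
        raise InputError(f"non-finite Cq in triplicate: {values}")
    if _sample_sd(values) <= sd_threshold:
        return QCResult(tuple(values), QC_PASS)
    mean = sum(values) / 3.0
    # farthest from the mean; ties broken toward the larger Cq value
    drop_idx = max(range(3), key=lambda i: (abs(values[i] - mean), values[i]))
    pair = tuple(v for i, v in enumerate(values) if i != drop_idx)
    if _sample_sd(pair) <= sd_threshold:
        return QCResult(pair, QC_OUTLIER_DROPPED)
    return QCResult((), QC_DISCARDED)


def relative_quantity(mean_cq: float, batch_max_mean_cq: float, efficiency: float) -> float:
    """Efficiency-corrected relative quantity ``Qr = (1+E) ** dCt`` with
    ``dCt = batch_max_mean_cq - mean_cq``.

    The batch maximum is the highest mean Cq in the sample's gene x region
    batch, so the least-expressed sample has Qr = 1 and one cycle of
    advantage is a factor (1+E).
    """
    if efficiency <= 0:
        raise InputError(f"efficiency must be > 0, got {efficiency}")
    if mean_cq > batch_max_mean_cq + 1e-9:
        raise OrderingError(
            f"mean_cq {mean_cq} exceeds batch max {batch_max_mean_cq}: "
            "batch maximum mis-computed"
        )
    return (1.0 + efficiency) ** (batch_max_mean_cq - mean_cq)


def normalization_factor(ref_qrs, method: str = "geometric_mean") -> float:
    """Per-sample normalization factor from the reference-gene Qr values.

    Default is the geometric mean; ``method="product"`` multiplies the
    reference quantities instead (a sensitivity-analysis variant). A single
    reference returns the value itself under either method.
    """
    vals = [float(v) for v in ref_qrs]
    if not vals:
        raise InputError("normalization_factor: empty reference list")
    if any(v <= 0 or not math.isfinite(v) for v in vals):
        raise InputError(f"reference quantities must be positive finite, got {vals}")
    if method == "geometric_mean":
        return math.exp(sum(math.log(v) for v in vals) / len(vals))
    if method == "product":
        return math.prod(vals)
    raise InputError(f"unknown normalization method {method!r}")


def _qc_sample_table(cq: pd.DataFrame, sd_threshold: float) -> pd.DataFrame:
    """Collapse the long Cq table to one row per sample with QC applied."""
    required = {"bee_id", "group", "region", "gene", "replicate", "cq"}
    missing = required - set(cq.columns)
    if missing:
        raise InputError(f"cq table missing columns: {sorted(missing)}")
    rows = []
    for (bee, group, region, gene), g in cq.groupby(
        ["bee_id", "group", "region", "gene"], sort=True
    ):
        vals = g["cq"].to_numpy(dtype=float)
        if vals.size != 3:
            raise InputError(
                f"sample ({bee}, {region}, {gene}) has {vals.size} replicates, expected 3"
            )
        res = triplicate_qc(vals, sd_threshold)
        rows.append(
            {
                "bee_id": bee,
                "group": group,
                "region": region,
                "gene": gene,
                "mean_cq": float(np.mean(res.retained)) if res.retained else np.nan,
                "qc_status": res.status,
                "n_retained": len(res.retained),
            }
        )
    return pd.DataFrame(rows)


def normalized_expression_table(
    cq: pd.DataFrame,
    primers: dict[str, PrimerSpec] | None = None,
    policy: dict[str, frozenset[str]] | None = None,
    *,
    sd_threshold: float = 0.3,
    nf_method: str = "geometric_mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full quantification: QC, per-batch dCt, Qr, and normalized expression.

    Input is the long Cq table (bee_id, group, region, gene, replicate, cq).
    Batches are gene x region across all bees of both groups; the batch
    reference is the highest retained mean Cq. Samples discarded by QC, or
    lacking every reference measurement, propagate as rows with NaN
    expression and an explanatory flag rather than disappearing.

    Returns ``(expression, qc_log)``: the per-sample expression table (target
    and reference genes; reference rows carry Qr but no normalized value)
    and the log of QC decisions.
    """
    primers = primers if primers is not None else TABLE_PRIMERS
    policy = policy if policy is not None else DEFAULT_POLICY
    samples = _qc_sample_table(cq, sd_threshold)
    qc_log = samples[["bee_id", "group", "region", "gene", "qc_status", "n_retained"]].copy()

    # batch reference: highest retained mean Cq per gene x region
    batch_max = (
        samples.dropna(subset=["mean_cq"])
        .groupby(["gene", "region"])["mean_cq"]
        .max()
        .rename("batch_max_cq")
    )
    samples = samples.merge(batch_max, left_on=["gene", "region"], right_index=True, how="left")

    effs = {g: p.efficiency for g, p in primers.items()}
    unknown = set(samples["gene"]) - set(effs)
    if unknown:
        raise InputError(f"no primer efficiency for genes: {sorted(unknown)}")
    samples["efficiency"] = samples["gene"].map(effs)
    samples["delta_cq"] = samples["batch_max_cq"] - samples["mean_cq"]
    samples["qr"] = np.where(
        samples["mean_cq"].notna(),
        (1.0 + samples["efficiency"]) ** samples["delta_cq"],
        np.nan,
    )

    # per-sample normalization factor from that bee/region's reference genes
    ref_rows = samples[samples["gene"].isin(REFERENCE_GENES)]
    ref_qr: dict[tuple[str, str], dict[str, float]] = {}
    for row in ref_rows.itertuples():
        if np.isfinite(row.qr):
            ref_qr.setdefault((row.bee_id, row.region), {})[row.gene] = row.qr

    factors = []
    flags = []
    for row in samples.itertuples():
        wanted = policy.get(row.region, frozenset())
        have = ref_qr.get((row.bee_id, row.region), {})
        avail = {g: v for g, v in have.items() if g in wanted}
        flag = ""
        if row.qc_status == QC_DISCARDED:
            flag = "discarded_qc"
        if not wanted:
            factors.append(np.nan)
            flags.append(flag or "no_reference_policy")
            continue
        if not avail:
            factors.append(np.nan)
            flags.append(flag or "missing_reference")
            continue
        if set(avail) != set(wanted) and not flag:
            missing = ",".join(sorted(set(wanted) - set(avail)))
            flag = f"partial_reference({missing})"
        factors.append(normalization_factor(list(avail.values()), nf_method))
        flags.append(flag)
    samples["normalization_factor"] = factors
    samples["flag"] = flags
    samples["is_reference"] = samples["gene"].isin(REFERENCE_GENES)
    samples["normalized_expression"] = np.where(
        ~samples["is_reference"],
        samples["qr"] / samples["normalization_factor"],
        np.nan,
    )
    cols = [
        "bee_id", "group", "region", "gene", "mean_cq", "delta_cq", "qr",
        "normalization_factor", "normalized_expression", "qc_status",
        "is_reference", "flag",
    ]
    return samples[cols].reset_index(drop=True), qc_log


def reference_stability_test(
    cq: pd.DataFrame,
    policy: dict[str, frozenset[str]] | None = None,
    *,
    sd_threshold: float = 0.3,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, frozenset[str]]]:
    """Screen reference genes for between-group stability, region by region.

    For each region and candidate reference gene, the post-QC mean Cq values
    are compared between the two groups with a pooled two-sample t-test. A
    reference that differs at ``alpha`` is removed from that region's
    normalization policy; a region is never left without a reference (the
    most stable candidate, largest p, is retained with a warning flag).

    Returns the per-(region, reference) report and the adjusted policy.
    """
    policy = policy if policy is not None else {r: REFERENCE_GENES for r in REGIONS}
    samples = _qc_sample_table(cq, sd_threshold).dropna(subset=["mean_cq"])
    groups = sorted(samples["group"].unique())
    if len(groups) != 2:
        raise InputError(f"stability test needs exactly 2 groups, got {groups}")
    report_rows = []
    adjusted: dict[str, frozenset[str]] = {}
    for region, wanted in policy.items():
        decisions: dict[str, tuple[float, bool]] = {}
        for gene in sorted(wanted):
            sub = samples[(samples["region"] == region) & (samples["gene"] == gene)]
            a = sub.loc[sub["group"] == groups[0], "mean_cq"].to_numpy()
            b = sub.loc[sub["group"] == groups[1], "mean_cq"].to_numpy()
            if a.size < 2 or b.size < 2:
                raise InputError(
                    f"stability test needs >= 2 bees per group for {gene}/{region}"
                )
            cmp = compare_groups(a, b, gene=gene, region=region)
            stable = cmp.p_value >= alpha
            decisions[gene] = (cmp.p_value, stable)
            report_rows.append(
                {
                    "region": region,
                    "reference": gene,
                    "t_statistic": cmp.t_statistic,
                    "df": cmp.df,
                    "p_value": cmp.p_value,
                    "stable": stable,
                }
            )
        keep = {g for g, (_, stable) in decisions.items() if stable}
        fallback = False
        if not keep:
            best = max(decisions, key=lambda g: decisions[g][0])
            keep = {best}
            fallback = True
            warnings.warn(
                f"{region}: no stable reference gene; falling back to {best}",
                stacklevel=2,
            )
        adjusted[region] = frozenset(keep)
        for row in report_rows:
            if row["region"] == region:
                row["retained"] = row["reference"] in keep
                row["fallback"] = fallback
    return pd.DataFrame(report_rows), adjusted


def compare_groups(
    a, b, *, gene: str | None = None, region: str | None = None
) -> GroupComparison:
    """Pooled-variance two-sample t-test (two-sided), df = n1 + n2 - 2.

    Zero pooled variance with equal means gives t = 0, p = 1; with unequal
    means the comparison is flagged infinite (t = +/-inf, p = 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("compare_groups needs >= 2 observations per group")
    df = int(a.size + b.size - 2)
    pooled_var = (
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    )
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            return GroupComparison(0.0, df, 1.0, a.mean(), b.mean(), a.size, b.size,
                                   gene=gene, region=region)
        t = math.inf if a.mean() > b.mean() else -math.inf
        return GroupComparison(t, df, 0.0, a.mean(), b.mean(), a.size, b.size,
                               gene=gene, region=region, infinite_t=True)
    res = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        float(res.statistic), df, float(res.pvalue),
        float(a.mean()), float(b.mean()), int(a.size), int(b.size),
        gene=gene, region=region,
    )


def compare_all(expression: pd.DataFrame) -> pd.DataFrame:
    """Learner vs non-learner comparison for every target gene x region.

    Operates on the normalized expression table; samples without a
    normalized value (discarded or unnormalizable) are left out of the test
    but counted in the output.
    """
    rows = []
    targets = expression[~expression["is_reference"]]
    for (gene, region), g in targets.groupby(["gene", "region"], sort=True):
        a = g.loc[
            (g["group"] == "LEARNER") & g["normalized_expression"].notna(),
            "normalized_expression",
        ].to_numpy()
        b = g.loc[
            (g["group"] == "NON_LEARNER") & g["normalized_expression"].notna(),
            "normalized_expression",
        ].to_numpy()
        cmp = compare_groups(a, b, gene=gene, region=region)
        rows.append(
            {
                "gene": gene,
                "region": region,
                "t_statistic": cmp.t_statistic,
                "df": cmp.df,
                "p_value": cmp.p_value,
                "mean_learner": cmp.mean_a,
                "mean_non_learner": cmp.mean_b,
                "n_learner": cmp.n_a,
                "n_non_learner": cmp.n_b,
                "fold_change": cmp.mean_a / cmp.mean_b if cmp.mean_b > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def fold_change_estimates(expression: pd.DataFrame) -> pd.DataFrame:
    """Per gene x region estimated learner/non-learner fold change and p-value."""
    cmp = compare_all(expression)
    cmp["log_fold_change"] = np.log(cmp["fold_change"])
    return cmp[["gene", "region", "fold_change", "log_fold_change", "p_value"]]
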