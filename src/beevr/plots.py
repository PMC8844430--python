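"""Basic figures: learning curves and expression boxplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

CURVE_STYLE = {"cs_plus": ("tab:red", "CS+"), "cs_minus": ("black", "CS-"), "nc": ("gray", "NC")}


def learning_curves(curves: pd.DataFrame, path: str | Path) -> None:
    """Per-category first-choice percentage curves with 95% CI bands."""
    cats = curves["category"].unique()
    fig, axes = plt.subplots(1, len(cats), figsize=(5 * len(cats), 4), squeeze=False)
    for ax, cat in zip(axes[0], cats):
        sub = curves[(curves["category"] == cat) & (curves["phase"] == "train")]
        for key, (color, label) in CURVE_STYLE.items():
            ax.plot(sub["trial"], 100 * sub[f"p_{key}"], color=color, marker="o", label=label)
            ax.fill_between(
                sub["trial"], 100 * sub[f"ci_low_{key}"], 100 * sub[f"ci_high_{key}"],
                color=color, alpha=0.15,
            )
        ax.set_title(cat.replace("_", "-").lower())
        ax.set_xlabel("trial")
        ax.set_ylabel("% of bees (first choice)")
        ax.set_ylim(0, 100)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def expression_boxplots(expression: pd.DataFrame, path: str | Path) -> None:
    """Normalized expression per gene x region, learners vs non-learners."""
    targets = expression[~expression["is_reference"].astype(bool)].dropna(
        subset=["normalized_expression"]
    )
    genes = sorted(targets["gene"].unique())
    regions = sorted(targets["region"].unique())
    fig, axes = plt.subplots(
        len(genes), len(regions), figsize=(3 * len(regions), 2.5 * len(genes)),
        squeeze=False,
    )
    for i, gene in enumerate(genes):
        for j, region in enumerate(regions):
            ax = axes[i][j]
            sub = targets[(targets["gene"] == gene) & (targets["region"] == region)]
            data = [
                sub.loc[sub["group"] == g, "normalized_expression"].to_numpy()
                for g in ("LEARNER", "NON_LEARNER")
            ]
            ax.boxplot(data, tick_labels=["L", "NL"], showmeans=True)
            ax.set_title(f"{gene} / {region}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
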