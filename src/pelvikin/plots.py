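"""Optional figures: Bland-Altman grids and per-task boxplots."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import OUTCOME_UNITS

_TASK_ORDER = ("SLS", "SD15", "SD20")


def bland_altman_grid(outcomes: pd.DataFrame, path: str | Path) -> None:
    """One Bland-Altman panel per outcome x task (mocap - phone)."""
    names = list(OUTCOME_UNITS)
    fig, axes = plt.subplots(
        len(names), len(_TASK_ORDER), figsize=(10, 3 * len(names)), squeeze=False
    )
    for i, outcome in enumerate(names):
        for j, task in enumerate(_TASK_ORDER):
            ax = axes[i][j]
            sub = outcomes[outcomes["task"] == task].pivot(
                index="participant", columns="source", values=outcome
            ).dropna()
            if sub.empty or {"mocap", "phone"} - set(sub.columns):
                ax.set_axis_off()
                continue
            diff = sub["mocap"] - sub["phone"]
            mean = 0.5 * (sub["mocap"] + sub["phone"])
            bias = float(diff.mean())
            sd = float(np.std(diff, ddof=1)) if len(diff) > 1 else 0.0
            ax.scatter(mean, diff, s=10, alpha=0.7)
            ax.axhline(bias, color="k", lw=1.5)
            for level in (bias - 1.96 * sd, bias + 1.96 * sd):
                ax.axhline(level, color="k", ls="--", lw=1)
            ax.set_title(f"{outcome} {task}", fontsize=9)
            if j == 0:
                ax.set_ylabel(f"diff ({OUTCOME_UNITS[outcome]})", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def task_boxplots(outcomes: pd.DataFrame, path: str | Path) -> None:
    """Boxplots of every outcome across the three tasks, per source."""
    names = list(OUTCOME_UNITS)
    fig, axes = plt.subplots(2, len(names), figsize=(3 * len(names), 6), squeeze=False)
    for r, source in enumerate(("mocap", "phone")):
        sub = outcomes[outcomes["source"] == source]
        for c, outcome in enumerate(names):
            ax = axes[r][c]
            data = [
                sub.loc[sub["task"] == task, outcome].dropna().to_numpy()
                for task in _TASK_ORDER
            ]
            ax.boxplot(data, tick_labels=_TASK_ORDER)
            ax.set_title(f"{source}: {outcome}", fontsize=9)
            ax.set_ylabel(OUTCOME_UNITS[outcome], fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
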