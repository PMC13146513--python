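"""Optional figures: Bland-Altman plots, age-response scatter, GWR box plots."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .agreement import BlandAltmanResult
from .stats import CurveFit


def bland_altman_plot(result: BlandAltmanResult, path: Path) -> Path:
    """Mean on x, DOT-ROI difference on y, bias and +/-1.96 SD lines."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.diffs, s=18, color="k")
    ax.axhline(result.bias, color="k", lw=2)
    for y in (result.loa_lower, result.loa_upper):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of ROI and DOT (HU)")
    ax.set_ylabel("DOT − ROI (HU)")
    ax.set_title(f"{result.region}: bias {result.bias:.2f} HU")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def age_response_plot(
    ages: np.ndarray, values: np.ndarray, fit: CurveFit, region: str, path: Path
) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ages, values, s=18, color="k")
    grid = np.linspace(max(ages.min(), 1.0), ages.max(), 200)
    ax.plot(grid, fit.predict(grid), color="tab:red")
    ax.set_xlabel("age (months)")
    ax.set_ylabel("HU")
    ax.set_title(f"{region} ({fit.form}, R² = {fit.r_squared:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def gwr_box_plot(gwr: pd.DataFrame, groups: pd.Series, path: Path) -> Path:
    """Per-formula box plots, young and old strata side by side."""
    g = gwr.assign(group=groups.loc[gwr["subject_id"]].to_numpy())
    formulas = list(dict.fromkeys(gwr["formula_id"]))
    fig, ax = plt.subplots(figsize=(max(8, len(formulas)), 4))
    data, positions, colors = [], [], []
    for i, fid in enumerate(formulas):
        for j, (grp, color) in enumerate([("young", "0.4"), ("old", "0.8")]):
            data.append(g[(g["formula_id"] == fid) & (g["group"] == grp)]["value"].to_numpy())
            positions.append(i * 3 + j)
            colors.append(color)
    boxes = ax.boxplot(data, positions=positions, widths=0.8, patch_artist=True)
    for patch, color in zip(boxes["boxes"], colors):
        patch.set_facecolor(color)
    ax.set_xticks([i * 3 + 0.5 for i in range(len(formulas))])
    ax.set_xticklabels(formulas, rotation=45, ha="right")
    ax.set_ylabel("GWR")
    ax.axhline(1.0, color="k", lw=0.5, ls=":")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
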