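"""Basic per-DV boxplot report (group comparison layout)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .features import DV_FOLLOWUP


def boxplot_features(
    df: pd.DataFrame,
    dvs: Sequence[str] = DV_FOLLOWUP,
    out_path: str | Path = "features_boxplot.png",
) -> Path:
    """One boxplot per DV, split by group; returns the written path."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dvs = [dv for dv in dvs if dv in df.columns]
    groups = sorted(df["group"].dropna().unique())
    ncols = min(4, max(1, len(dvs)))
    nrows = (len(dvs) + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 3.0 * nrows),
                             squeeze=False)
    for ax in axes.ravel()[len(dvs):]:
        ax.set_visible(False)
    for ax, dv in zip(axes.ravel(), dvs):
        data = [df.loc[df["group"] == g, dv].dropna() for g in groups]
        ax.boxplot(data, tick_labels=groups)
        ax.set_title(dv, fontsize=9)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path
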