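"""Plot-ready tables and figure rendering for pipeline outputs.

Every figure is emitted first as a plain table (testable, byte-stable given
identical inputs); rendering to PNG via matplotlib is a cosmetic final step.
Emitters never mutate the statistical tables they are given.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

NEG_LOG10_P_CAP = 300.0  # y-axis cap where p underflows to 0


def volcano_data(differential: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Volcano-plot table: x = log2 fold change, y = -log10 raw p, q-based flag.

    Rows without an abundance test (filtered out or undefined) are omitted.
    p = 0 is capped at a documented maximum so the point stays plottable.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    table = differential.dropna(subset=["abundance_p"])
    with np.errstate(divide="ignore"):
        y = -np.log10(table["abundance_p"].to_numpy(float))
    out = pd.DataFrame({
        "protein_id": table.index,
        "log2_fold_change": table["log2_fold_change"].to_numpy(float),
        "neg_log10_p": np.minimum(y, NEG_LOG10_P_CAP),
        "significant": (table["abundance_q"] < alpha).to_numpy(bool),
    })
    return out


def heatmap_data(
    zscores: pd.DataFrame,
    metadata: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Heatmap table with columns ordered by group, then ascending plastic mass.

    Ties in mass break by sample_id so the ordering is reproducible. Returns
    (reordered z-score matrix, column annotation with a square-root-scale
    plastic-mass track for display next to the heatmap).
    """
    meta = metadata.set_index("sample_id").loc[list(zscores.columns)].reset_index()
    meta["_grp"] = pd.Categorical(meta["group"], categories=["low", "high"], ordered=True)
    meta = meta.sort_values(["_grp", "plastic_mass", "sample_id"], kind="stable")
    order = meta["sample_id"].tolist()
    tracks = pd.DataFrame({
        "sample_id": order,
        "group": meta["group"].to_numpy(),
        "plastic_mass": meta["plastic_mass"].to_numpy(float),
        "sqrt_plastic_mass": np.sqrt(meta["plastic_mass"].to_numpy(float)),
    })
    return zscores[order], tracks


def render_volcano(volcano: pd.DataFrame, path: str | Path, alpha: float = 0.05) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sig = volcano["significant"]
    ax.scatter(volcano.loc[~sig, "log2_fold_change"], volcano.loc[~sig, "neg_log10_p"],
               s=6, c="grey", alpha=0.6, lw=0)
    ax.scatter(volcano.loc[sig, "log2_fold_change"], volcano.loc[sig, "neg_log10_p"],
               s=8, c="crimson", alpha=0.8, lw=0)
    if sig.any():
        ax.axhline(volcano.loc[sig, "neg_log10_p"].min(), ls="--", lw=0.8, c="black")
    ax.set_xlabel("log2 fold change (high vs low)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_heatmap(zscores: pd.DataFrame, tracks: pd.DataFrame, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_mass, ax_hm) = plt.subplots(
        2, 1, figsize=(max(4, 0.22 * zscores.shape[1]), 6),
        gridspec_kw={"height_ratios": [1, 8]}, sharex=True)
    ax_mass.bar(range(zscores.shape[1]), tracks["sqrt_plastic_mass"], color="steelblue")
    ax_mass.set_ylabel("sqrt mass (g)")
    im = ax_hm.imshow(zscores.to_numpy(float), aspect="auto", cmap="RdBu_r",
                      vmin=-3, vmax=3, interpolation="nearest")
    ax_hm.set_xticks(range(zscores.shape[1]))
    ax_hm.set_xticklabels(zscores.columns, rotation=90, fontsize=5)
    ax_hm.set_yticks([])
    fig.colorbar(im, ax=ax_hm, shrink=0.6, label="Z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_pca(scores: pd.DataFrame, metadata: pd.DataFrame,
               explained: np.ndarray, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = metadata.set_index("sample_id")["group"].reindex(scores.index)
    fig, ax = plt.subplots(figsize=(5, 4))
    for grp, color in (("low", "tab:blue"), ("high", "tab:orange")):
        mask = (groups == grp).to_numpy()
        ax.scatter(scores.loc[mask, "PC1"], scores.loc[mask, "PC2"], label=grp, c=color)
    ax.set_xlabel(f"PC1 ({100 * explained[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * explained[1]:.1f}%)" if len(explained) > 1 else "PC2")
    ax.legend(title="exposure")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
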