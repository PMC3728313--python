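"""Optional matplotlib figures for sweep results."""

from __future__ import annotations

import pandas as pd


def plot_wedge(df: pd.DataFrame, path: str) -> None:
    """Scatter of h2_narrow and c2_final against (rMZ, rDZ), colored by k."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5), sharex=True, sharey=True)
    for ax, col, label in zip(axes, ("h2_narrow", "c2_final"),
                              ("narrow-sense h²", "final-level c²")):
        sc = ax.scatter(df["r_dz"], df["r_mz"], c=df[col], s=12,
                        cmap="viridis", vmin=0, vmax=1)
        ax.set_xlabel("rDZ")
        ax.set_title(label)
        fig.colorbar(sc, ax=ax)
    axes[0].set_ylabel("rMZ")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sweep(df: pd.DataFrame, path: str) -> None:
    """Phantom heritability against the swept parameter, one line per k."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for k, sub in df.groupby("k"):
        sub = sub.sort_values("swept_value")
        ax.errorbar(sub["swept_value"], sub["phantom"],
                    yerr=2 * sub["phantom_se"], marker="o", label=f"k={k}")
    ax.set_xlabel(df["panel"].iloc[0])
    ax.set_ylabel("phantom heritability")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
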