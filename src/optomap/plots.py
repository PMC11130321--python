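"""Minimal rendered-figure helpers (matplotlib, Agg-safe)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .circuit import InputMatrix  # noqa: E402
from .profiles import AxonProfile  # noqa: E402

__all__ = ["plot_input_matrix", "plot_axon_profile"]


def plot_input_matrix(matrix: InputMatrix, path: str | Path) -> None:
    """Heat map of mean response amplitude per (layer, cell class)."""
    wide = matrix.table["mean_amplitude"].unstack(level="cell_class")
    fig, ax = plt.subplots(figsize=(4, 3))
    im = ax.imshow(wide.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(wide.shape[1]), wide.columns)
    ax.set_yticks(range(wide.shape[0]), wide.index)
    ax.set_title(f"{matrix.input_source} input strength")
    fig.colorbar(im, ax=ax, label="mean amplitude")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_axon_profile(profile: AxonProfile, path: str | Path) -> None:
    """Normalized fluorescence versus depth with layer boundaries."""
    fig, ax = plt.subplots(figsize=(3, 4))
    ax.plot(profile.intensity, profile.depth)
    ax.invert_yaxis()
    for b in profile.layer_table.bounds[1:-1]:
        ax.axhline(b, color="gray", lw=0.5, ls="--")
    ax.set_xlabel("intensity (AU)")
    ax.set_ylabel("depth from pia (µm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
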