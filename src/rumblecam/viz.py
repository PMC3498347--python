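"""Plot helpers: acoustic-map heatmaps and descriptor matrices."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .beamforming import AcousticMap
from .classification import LPCDescriptor


def plot_acoustic_map(amap: AcousticMap, path=None, marks: dict | None = None):
    """SPL heatmap of the image plane; ``marks`` = {label: (x, y)}."""
    plane = amap.plane
    fig, ax = plt.subplots(figsize=(6, 4.5))
    extent = [-plane.width / 2, plane.width / 2, -plane.height / 2, plane.height / 2]
    im = ax.imshow(amap.spl_grid, origin="lower", extent=extent, cmap="inferno")
    fig.colorbar(im, ax=ax, label="effective SPL (dB re 20 µPa)")
    px, py = amap.peak_position[:2]
    ax.plot(px, py, "c+", ms=12, label=f"peak {amap.peak_db:.1f} dB")
    for name, (x, y) in (marks or {}).items():
        ax.plot(x, y, "wo", mfc="none")
        ax.annotate(name, (x, y), color="w", fontsize=8,
                    textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.legend(loc="upper right", fontsize=8)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_descriptor_matrix(descriptors: list[LPCDescriptor], path=None):
    """Descriptor-per-column heatmap, calls grouped by class."""
    order = sorted(range(len(descriptors)), key=lambda i: descriptors[i].label or "")
    mat = np.stack([descriptors[i].vector for i in order], axis=1)
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(mat, aspect="auto", origin="lower", cmap="jet")
    fig.colorbar(im, ax=ax, label="avg LPC envelope (dB)")
    ax.set_xlabel("call (grouped by class)")
    ax.set_ylabel("descriptor component (0–500 Hz)")
    labels = [descriptors[i].label for i in order]
    if labels and labels[0] is not None:
        first_oral = next((j for j, l in enumerate(labels) if l == "oral"), None)
        if first_oral is not None:
            ax.axvline(first_oral - 0.5, color="w", lw=1)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
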