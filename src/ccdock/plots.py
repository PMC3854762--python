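"""Figure-style renderings: NII heat maps and IR-signature scatters."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def nii_heatmap(nii: pd.DataFrame, path: str | Path,
                class_order: Sequence[str] | None = None,
                title: str = "Normalized interaction index") -> None:
    """Heat map of an NII matrix (receptors on rows, ligands on columns),
    optionally reordered by a class-sorted protein list."""
    m = nii if class_order is None else nii.loc[class_order, class_order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(m.to_numpy(dtype=float), vmin=0, vmax=1, cmap="viridis")
    ax.set_xlabel("ligand")
    ax.set_ylabel("receptor")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="NII")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def signature_scatter(signatures, path: str | Path,
                      sd_bins: Sequence[float] = (1.0, 3.0, 5.0),
                      native: str | None = None) -> None:
    """Mean IR vs mean AUC of candidate partners, coloured by rank-spread
    bin; the native partner, when named, is circled."""
    colors = ["black", "tab:blue", "tab:cyan", "gold"]
    fig, ax = plt.subplots(figsize=(5, 4))
    for s in signatures:
        k = int(np.searchsorted(sd_bins, s.sd_ir, side="right"))
        ax.scatter(s.mean_auc, s.mean_ir, c=colors[min(k, 3)], s=18)
        if native is not None and s.candidate == native:
            ax.scatter(s.mean_auc, s.mean_ir, facecolors="none",
                       edgecolors="red", s=120)
    ax.set_xlabel("mean AUC over environments")
    ax.set_ylabel("mean interaction rank")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
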