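"""Optional figure output: displacement heat maps and summary curves."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .piv import DisplacementField, MobilityCurve

__all__ = ["save_heatmap", "save_mobility_curve"]


def save_heatmap(fields: Sequence[DisplacementField], path) -> Path:
    """Render the mean displacement-magnitude map (um) of one movie.

    The plotted quantity is exactly the block-averaged displacement
    magnitude; the colormap is presentation only.
    """
    mags = []
    for f in fields:
        m = np.hypot(f.u, f.v) * f.pixel_size
        m[~f.valid] = np.nan
        mags.append(m)
    mean_map = np.nanmean(np.stack(mags), axis=0)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(mean_map, origin="upper", cmap="inferno")
    fig.colorbar(im, ax=ax, label="displacement (um)")
    ax.set_xlabel("block x")
    ax.set_ylabel("block y")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def save_mobility_curve(curve: MobilityCurve, path) -> Path:
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(curve.elapsed_times, curve.values, "o-")
    ax.set_xlabel("elapsed time (min)")
    ax.set_ylabel(f"normalized mobility (lag {curve.lag:g} s)")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
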