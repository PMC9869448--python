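"""Territory map rendering: PNG via matplotlib and plain-text PGM."""

from __future__ import annotations

import pathlib

import numpy as np

__all__ = ["render", "save_pgm"]

UNOCCUPIED = -1
# olive for dispersed/unoccupied land, as in the published maps
_UNOCCUPIED_RGB = (0.42, 0.43, 0.18)


def community_color(cid: int) -> tuple[float, float, float]:
    """Deterministic colour for a community id."""
    import matplotlib.cm as cm
    return cm.tab20(cid % 20)[:3]


def render(owner: np.ndarray, path: str | pathlib.Path) -> None:
    """Write a territory map: one colour per community, olive where
    unoccupied.  Pixel counts per colour equal territory cell counts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rgb = np.empty(owner.shape + (3,))
    rgb[:] = _UNOCCUPIED_RGB
    for cid in np.unique(owner):
        if cid == UNOCCUPIED:
            continue
        rgb[owner == cid] = community_color(int(cid))
    fig, ax = plt.subplots(figsize=(6, 6 * owner.shape[0] / owner.shape[1]))
    ax.imshow(rgb, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def save_pgm(owner: np.ndarray, path: str | pathlib.Path) -> None:
    """Plain-text PGM (P2) of the owner raster; unoccupied mapped to 0 and
    community ids to id+1."""
    grey = (owner + 1).astype(np.int64)
    maxval = max(1, int(grey.max()))
    lines = [f"P2", f"{owner.shape[1]} {owner.shape[0]}", str(maxval)]
    for row in grey:
        lines.append(" ".join(str(int(v)) for v in row))
    pathlib.Path(path).write_text("\n".join(lines) + "\n")
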