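"""Configuration-space plot: samples in the (m, U) plane with RCP contours."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import region_boundaries, u_from_m_rcp


def configuration_space_arrays(
    contours: Sequence[float] = (1.0, 2.0, 5.0, 20.0),
    n_grid: int = 401,
) -> dict:
    """Boundary curves and RCP contour polylines for the (m, U) plane.

    Returned as plain arrays so tests can assert the geometry (ordering of
    the dispersive/random/conservative curves, feasibility of contour
    points) without rendering pixels.
    """
    m = np.linspace(0.0, 1.0, n_grid)
    disp, rand_, cons = np.array([region_boundaries(x) for x in m]).T
    contour_lines = {}
    m_inner = m[(m > 0.0) & (m < 1.0)]
    for r in contours:
        contour_lines[r] = np.array([(x, u_from_m_rcp(x, r)) for x in m_inner])
    return {
        "m": m,
        "dispersive": disp,
        "random": rand_,
        "conservative": cons,
        "contours": contour_lines,
    }


def plot_configuration_space(
    samples: Sequence[tuple[str, float, float]] = (),
    contours: Sequence[float] = (1.0, 2.0, 5.0, 20.0),
    path: str | None = None,
    ax=None,
):
    """Render the (m, U) plane with boundaries, contours and sample points.

    ``samples`` is a sequence of ``(label, m, U)`` triples.  Returns the
    matplotlib figure; writes to ``path`` (PNG/SVG by extension) if given.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    geom = configuration_space_arrays(contours)
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 5))
    else:
        fig = ax.figure
    m = geom["m"]
    ax.plot(m, geom["conservative"], "k-", lw=1.2, label="conservative (U = 1 - m)")
    ax.plot(m, geom["dispersive"], "k-", lw=1.2, label="dispersive (U = max(1-2m, 0))")
    ax.plot(m, geom["random"], "k--", lw=1.0, label="random (U = (1-m)$^2$)")
    for r, line in geom["contours"].items():
        ax.plot(line[:, 0], line[:, 1], lw=0.7, color="tab:gray", alpha=0.8)
        mid = line[len(line) // 2]
        ax.annotate(f"RCP={r:g}", mid, fontsize=7, color="tab:gray")
    for label, sm, su in samples:
        ax.plot([sm], [su], "*", ms=10)
        ax.annotate(label, (sm, su), fontsize=8, xytext=(3, 3),
                    textcoords="offset points")
    ax.set_xlabel("methylation frequency m")
    ax.set_ylabel("unmethylated-dyad frequency U")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
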