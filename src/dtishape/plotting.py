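"""Shape-triangle (barycentric) plots of tensor shape metrics."""

from __future__ import annotations

import numpy as np

from .tensor import shape_triangle_coords

__all__ = ["plot_shape_triangle"]


def plot_shape_triangle(metrics_by_name, ax=None, **scatter_kw):
    """Scatter (cl, cp, cs) triples in the barycentric shape triangle.

    Parameters
    ----------
    metrics_by_name : mapping of str -> (cl, cp, cs) arrays or ShapeMetrics
        One scatter series per entry (e.g. one per ROI).
    ax : matplotlib Axes, optional

    The triangle has the pure-linear tensor (stick) at the bottom-left
    corner, pure-planar (disc) at the bottom-right and pure-spherical
    (ball) at the apex.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    corners = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2], [0.0, 0.0]])
    ax.plot(corners[:, 0], corners[:, 1], color="0.3", lw=1)
    for name, m in metrics_by_name.items():
        x, y = shape_triangle_coords(m) if hasattr(m, "cl") else \
            shape_triangle_coords(*m)
        ax.scatter(np.atleast_1d(x), np.atleast_1d(y), label=str(name),
                   s=scatter_kw.pop("s", 12), **scatter_kw)
    ax.text(-0.02, -0.04, "linear", ha="left", va="top")
    ax.text(1.02, -0.04, "planar", ha="right", va="top")
    ax.text(0.5, np.sqrt(3) / 2 + 0.03, "spherical", ha="center")
    ax.set_xlim(-0.08, 1.08)
    ax.set_ylim(-0.12, 1.0)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(loc="upper right", fontsize=8, frameon=False)
    return ax
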