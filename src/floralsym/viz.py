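"""Shape-change diagrams and canonical-variate score plots.

Shape differences (e.g. a group mean versus the grand mean) are shown by
warping an outline drawing with the thin-plate spline interpolant that
maps the reference landmarks to the displaced ones, with the displacement
exaggerated by a configurable factor (default 15) to make subtle floral
shape changes visible. CV score plots show the organs' scores on the
first two canonical variates together with 95% confidence ellipses for
the group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Ellipse
from scipy.interpolate import RBFInterpolator

from .inference import CVAResult

__all__ = ["WarpSpec", "tps_warp", "shape_difference_plot", "cv_ellipse_plot"]


@dataclass
class WarpSpec:
    """A thin-plate-spline warp of an outline between two shapes.

    ``reference`` and ``target`` are (k, 2) landmark arrays; ``outline``
    is an ordered polyline in the reference frame. The warp maps each
    reference landmark to reference + exaggeration * (target - reference).
    """

    reference: np.ndarray
    target: np.ndarray
    outline: np.ndarray
    exaggeration: float = 15.0

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        self.outline = np.asarray(self.outline, dtype=float)
        if self.reference.shape != self.target.shape:
            raise ValueError("reference and target must have equal landmark counts")
        if self.exaggeration <= 0:
            raise ValueError("exaggeration must be positive")


def _check_nondegenerate(reference: np.ndarray) -> None:
    if len(np.unique(reference, axis=0)) != len(reference):
        raise ValueError("duplicate reference landmarks: TPS kernel is singular")
    centered = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise ValueError("collinear reference landmarks: TPS kernel is singular")


def tps_warp(spec: WarpSpec) -> np.ndarray:
    """Warp the outline through the exaggerated thin-plate spline.

    The interpolant maps reference landmarks exactly onto
    reference + exaggeration * (target - reference); the outline polyline
    is mapped through it. An affine difference between target and
    reference yields that affine map (zero bending energy); a zero
    difference yields the identity.
    """
    _check_nondegenerate(spec.reference)
    displaced = spec.reference + spec.exaggeration * (spec.target - spec.reference)
    interp = RBFInterpolator(
        spec.reference, displaced, kernel="thin_plate_spline", degree=1
    )
    return interp(spec.outline)


def shape_difference_plot(
    spec: WarpSpec,
    ax: plt.Axes | None = None,
    reference_style: dict | None = None,
    warped_style: dict | None = None,
) -> plt.Axes:
    """Plot the reference outline with its warped (exaggerated) counterpart."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    warped = tps_warp(spec)
    ax.plot(*spec.outline.T, **({"color": "0.6", "lw": 1} | (reference_style or {})))
    ax.plot(*warped.T, **({"color": "C3", "lw": 1.5} | (warped_style or {})))
    ax.set_aspect("equal")
    ax.set_axis_off()
    return ax


def cv_ellipse_plot(
    result: CVAResult,
    ax: plt.Axes | None = None,
    conf_label: str = "95% confidence ellipses for group means",
):
    """Scatter of CV1-CV2 scores with group-mean confidence ellipses.

    Returns the figure and the numeric ellipse-parameter table (group,
    center, semi-axes, orientation). With a single retained axis, a 1-D
    strip plot of CV1 scores is drawn instead and the table is empty.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure

    scores = result.scores
    groups = result.groups
    if scores.shape[1] < 2:
        ax.plot(scores[:, 0], np.zeros(len(scores)), "|", color="0.4")
        for i, g in enumerate(groups):
            ax.plot(result.group_means[i, 0], 0.0, "o", ms=6)
        ax.set_xlabel("CV1")
        ax.set_yticks([])
        ax.set_title("single canonical axis retained: 1-D score plot")
        return fig, pd.DataFrame()

    cmap = plt.get_cmap("viridis", len(groups))
    ellipses = result.ellipses if result.ellipses is not None else pd.DataFrame()
    # recover per-group membership from group means (scores carry no labels)
    for i, g in enumerate(groups):
        color = cmap(i)
        ax.plot(*result.group_means[i, :2], "o", color=color, ms=6)
        row = ellipses[ellipses["group"] == g] if len(ellipses) else None
        if row is not None and len(row):
            r = row.iloc[0]
            ax.add_patch(
                Ellipse(
                    (r["center_1"], r["center_2"]),
                    width=2 * r["semi_major"], height=2 * r["semi_minor"],
                    angle=r["angle_deg"], facecolor=color, alpha=0.3,
                    edgecolor=color, label=str(g),
                )
            )
    ax.scatter(scores[:, 0], scores[:, 1], s=6, c="0.7", zorder=0)
    ax.set_xlabel("CV1")
    ax.set_ylabel("CV2")
    ax.legend(title=conf_label, fontsize=8, loc="best")
    ax.set_aspect("equal")
    return fig, ellipses
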