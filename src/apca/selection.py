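"""Choosing the asymmetric weights (a, b).

The weights are selected by the classification criterion: a candidate
(a, b) is feasible when the case and control samples are linearly
separable in the plane spanned by the factor loadings of the first two
components (FL1 vs FL2). Among feasible candidates the pair with the
largest normalised separation margin wins; ties break towards smaller
b, then smaller a, for determinism.

Separability and margin are computed geometrically: two point clouds in
the plane are linearly separable exactly when their convex hulls are
disjoint, and the largest achievable hard margin is half the minimum
distance between the hulls. The margin is reported scale-free, divided
by the root-mean-square spread of all points about their centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint

from .io import CASE, CONTROL, ExpressionMatrix
from .core import APCAParams, apca

#: Grids used when no preset (a, b) is given: a sweeps (0, 1) uniformly,
#: b covers unity (plain PCA weighting) up to strongly mean-dominated.
DEFAULT_A_GRID = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))
DEFAULT_B_GRID = (1.0, 2.0, 5.0, 10.0, 20.0, 30.0)


@dataclass
class SelectionResult:
    """Outcome of the (a, b) search."""

    chosen: APCAParams | None
    feasible: list[tuple[float, float, float]] = field(default_factory=list)
    status: str = "ok"  # "ok" | "infeasible"


def separable(fl1: np.ndarray, fl2: np.ndarray,
              labels: list[str]) -> tuple[bool, float]:
    """Test strict linear separability of the two classes in the FL plane.

    Returns ``(flag, margin)``: flag is True when a separating line with
    strictly positive margin exists; margin is the hard margin (half the
    convex-hull distance) divided by the pooled RMS point spread, so it
    is invariant to a common rescaling of both axes. Degenerate input
    (all points identical) is not separable and has margin 0.
    """
    fl1 = np.asarray(fl1, float)
    fl2 = np.asarray(fl2, float)
    lab = np.asarray(labels)
    if fl1.shape != fl2.shape or len(lab) != len(fl1):
        raise ValueError("fl1, fl2 and labels must have equal length")
    pts = np.column_stack([fl1, fl2])
    spread = float(np.sqrt(np.mean(np.sum((pts - pts.mean(axis=0)) ** 2, axis=1))))
    if spread == 0:
        return False, 0.0
    hull_ctrl = MultiPoint(pts[lab == CONTROL]).convex_hull
    hull_case = MultiPoint(pts[lab == CASE]).convex_hull
    dist = float(hull_ctrl.distance(hull_case))
    if dist <= 0 or hull_ctrl.intersects(hull_case):
        return False, 0.0
    return True, (dist / 2.0) / spread


def grid_search(x: ExpressionMatrix,
                a_grid: tuple[float, ...] = DEFAULT_A_GRID,
                b_grid: tuple[float, ...] = DEFAULT_B_GRID,
                mode: str = "orthonormal") -> SelectionResult:
    """Run APCA over an (a, b) grid and keep separable configurations.

    The full decomposition is recomputed per grid point and FL1/FL2
    separability tested. The chosen parameters maximise the margin;
    exact ties resolve to smaller b, then smaller a. An empty feasible
    set is reported with status ``"infeasible"`` rather than an error —
    the caller decides how to proceed.
    """
    if not a_grid or not b_grid:
        raise ValueError("grids must be non-empty")
    if not all(0 < a < 1 for a in a_grid):
        raise ValueError("all a values must lie in (0, 1)")
    feasible: list[tuple[float, float, float]] = []
    for b in b_grid:
        for a in a_grid:
            dec = apca(x, APCAParams(a=float(a), b=float(b)), mode=mode)
            if dec.factor_loadings.shape[1] < 2:
                continue
            ok, margin = separable(dec.factor_loadings[:, 0],
                                   dec.factor_loadings[:, 1], x.labels)
            if ok:
                feasible.append((float(a), float(b), margin))
    if not feasible:
        return SelectionResult(chosen=None, feasible=[], status="infeasible")
    best = max(feasible, key=lambda t: (t[2], -t[1], -t[0]))
    return SelectionResult(chosen=APCAParams(a=best[0], b=best[1]),
                           feasible=feasible, status="ok")
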