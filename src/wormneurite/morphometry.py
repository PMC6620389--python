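"""Sharp-bend and bead/bleb detection along the classified main branch.

Sharp bends (kinks) are abrupt direction changes of the sensory dendrite.
For every interior node, the nodes within 2 µm of accumulated arclength on
each side are fitted with a line per side (total-least-squares principal
direction, so the fit is axis-independent); the angle subtended by the two
outward directions is the node's turning angle — 180° on a straight run,
smaller at a kink.  Nodes with an angle below a threshold (155° by default)
are bend candidates; candidates are selected sequentially from the sharpest,
and after each selection all candidates within a 4 µm arclength neighborhood
are suppressed (non-maximum suppression), preventing one physical kink from
being counted more than once.

Beads/blebs are focal enlargements of the process.  The local thickness
(mean radius in an 8 µm window) is subtracted from the node radii; residual
maxima exceeding 2 standard deviations of the residuals are counted
sequentially under the same suppression scheme.

A B-spline curvature profile of the main branch is exposed as a diagnostic
only; it is never used for the bend counts (windowed line fits are more
robust to tracing noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import splev, splprep

from .classification import ClassifiedTree

__all__ = [
    "MorphConfig",
    "BendEvent",
    "BeadEvent",
    "MainBranchGeometry",
    "node_angles",
    "detect_bends",
    "bend_density",
    "threshold_sweep",
    "local_thickness_residual",
    "detect_beads",
    "spline_curvature",
]


@dataclass(frozen=True)
class MorphConfig:
    """Detection thresholds, all in physical units.

    bend_window : µm of accumulated arclength per side used for the line fits
    bend_threshold : degrees; angles below it are bend candidates
    bend_nms : µm suppression neighborhood around each selected bend
    thickness_window : µm window for the local-thickness estimate
    bead_sd_multiplier : residual must exceed this many residual SDs
    bead_nms : µm suppression neighborhood around each selected bead
    bead_sd_on_residuals : SD from residuals (default) or raw radii
    spline_smoothing : smoothing factor for the diagnostic spline profile
    """

    bend_window: float = 2.0
    bend_threshold: float = 155.0
    bend_nms: float = 4.0
    thickness_window: float = 8.0
    bead_sd_multiplier: float = 2.0
    bead_nms: float = 4.0
    bead_sd_on_residuals: bool = True
    spline_smoothing: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.bend_threshold < 180:
            raise ValueError("bend_threshold must be in (0, 180) degrees")
        for name in ("bend_window", "bend_nms", "thickness_window",
                     "bead_sd_multiplier", "bead_nms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class BendEvent:
    node_id: int
    angle: float      # degrees in (0, 180]
    arclength: float  # µm along main branch from the root end


@dataclass(frozen=True)
class BeadEvent:
    node_id: int
    excess_radius: float  # µm above the local thickness
    arclength: float


@dataclass(frozen=True)
class MainBranchGeometry:
    """Main-branch polyline: points (N,3) µm, radii (N,) µm, node ids (N,)."""

    points: np.ndarray
    radii: np.ndarray
    node_ids: np.ndarray

    @classmethod
    def from_classified(cls, ct: ClassifiedTree) -> "MainBranchGeometry":
        ids = np.array(ct.main_branch)
        pts = np.array([ct.tree.nodes[i].position for i in ct.main_branch])
        rad = np.array([ct.tree.nodes[i].radius for i in ct.main_branch])
        return cls(points=pts, radii=rad, node_ids=ids)

    @property
    def arclengths(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def length(self) -> float:
        return float(self.arclengths[-1])


def _as_geometry(branch) -> MainBranchGeometry:
    if isinstance(branch, MainBranchGeometry):
        return branch
    if isinstance(branch, ClassifiedTree):
        return MainBranchGeometry.from_classified(branch)
    pts = np.asarray(branch, dtype=float)
    return MainBranchGeometry(
        points=pts,
        radii=np.zeros(len(pts)),
        node_ids=np.arange(len(pts)),
    )


def _principal_direction(points: np.ndarray, origin: np.ndarray) -> np.ndarray | None:
    """Unit principal direction of ``points``, oriented away from ``origin``."""
    centered = points - points.mean(axis=0)
    if np.allclose(centered, 0):
        return None
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    away = points[-1] - origin  # farthest-from-node point sets the orientation
    if np.dot(d, away) < 0:
        d = -d
    return d


def node_angles(branch, window: float = 2.0) -> np.ndarray:
    """Per-node turning angle (degrees) from windowed line fits.

    For each node with at least two neighbors within ``window`` µm of
    accumulated arclength on each side, a total-least-squares line is
    fitted per side (node included), both directions oriented away from
    the node, and the subtended angle returned via the numerically stable
    ``atan2(|u x v|, u.v)`` — a straight run gives 180°.  Nodes with an
    incomplete window (within ``window`` of either end) get NaN: one-sided
    fits bias angles.
    """
    geom = _as_geometry(branch)
    pts, s = geom.points, geom.arclengths
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 nodes to compute angles")
    angles = np.full(n, np.nan)
    for i in range(1, n - 1):
        if s[i] < window or geom.length - s[i] < window:
            continue  # incomplete window
        up = np.nonzero((s < s[i]) & (s >= s[i] - window))[0]
        dn = np.nonzero((s > s[i]) & (s <= s[i] + window))[0]
        if len(up) < 2 or len(dn) < 2:
            continue
        # order each side from the node outward; include the node itself
        u_pts = pts[np.concatenate([[i], up[::-1]])]
        d_pts = pts[np.concatenate([[i], dn])]
        u = _principal_direction(u_pts, pts[i])
        v = _principal_direction(d_pts, pts[i])
        if u is None or v is None:
            continue  # degenerate coincident points
        cross = np.linalg.norm(np.cross(u, v))
        dot = float(np.dot(u, v))
        angles[i] = np.degrees(np.arctan2(cross, dot))
    return angles


def _greedy_nms(
    order_idx: np.ndarray, arclengths: np.ndarray, nms: float
) -> list[int]:
    """Sequential selection by ``order_idx`` priority with arclength suppression."""
    selected: list[int] = []
    suppressed = np.zeros(len(arclengths), dtype=bool)
    for i in order_idx:
        if suppressed[i]:
            continue
        selected.append(int(i))
        suppressed |= np.abs(arclengths - arclengths[i]) <= nms
    return selected


def detect_bends(branch, cfg: MorphConfig | None = None) -> list[BendEvent]:
    """Detect sharp bends: threshold on turning angle + non-maximum suppression.

    Candidates are nodes with angle below ``cfg.bend_threshold``; they are
    selected sequentially starting with the sharpest (smallest angle), and
    every candidate within ``cfg.bend_nms`` µm of a selection is excluded
    from further selection.  Events return sorted by arclength.
    """
    cfg = cfg or MorphConfig()
    geom = _as_geometry(branch)
    angles = node_angles(geom, cfg.bend_window)
    return _select_bends(geom, angles, cfg.bend_threshold, cfg.bend_nms)


def _select_bends(
    geom: MainBranchGeometry,
    angles: np.ndarray,
    threshold: float,
    nms: float,
) -> list[BendEvent]:
    s = geom.arclengths
    cand = np.nonzero(angles < threshold)[0]
    if len(cand) == 0:
        return []
    order = cand[np.argsort(angles[cand], kind="stable")]
    picked = _greedy_nms(order, s, nms)
    events = [
        BendEvent(
            node_id=int(geom.node_ids[i]),
            angle=float(angles[i]),
            arclength=float(s[i]),
        )
        for i in picked
    ]
    events.sort(key=lambda e: e.arclength)
    _assert_separation([e.arclength for e in events], nms)
    return events


def _assert_separation(positions: list[float], nms: float) -> None:
    p = np.sort(np.asarray(positions))
    if len(p) > 1 and np.min(np.diff(p)) <= nms:
        raise AssertionError(
            "non-maximum suppression violated: events closer than the window"
        )


def bend_density(events: list, main_length: float) -> float:
    """Events per µm of main branch."""
    if main_length <= 0:
        raise ValueError("main branch length must be positive")
    return len(events) / main_length


def threshold_sweep(
    branch, cfg: MorphConfig | None = None,
    thresholds=(135.0, 140.0, 145.0, 150.0, 155.0, 160.0, 165.0),
) -> dict[float, float]:
    """Bend density per angle threshold, identical NMS throughout.

    Loosening the threshold only adds (weaker) candidates, so the density
    is non-decreasing in the threshold.
    """
    cfg = cfg or MorphConfig()
    geom = _as_geometry(branch)
    angles = node_angles(geom, cfg.bend_window)  # shared across thresholds
    out = {}
    for t in thresholds:
        if not 0 < t < 180:
            raise ValueError(f"threshold {t} outside (0, 180)")
        events = _select_bends(geom, angles, float(t), cfg.bend_nms)
        out[float(t)] = bend_density(events, geom.length)
    return out


def local_thickness_residual(branch, window: float = 8.0) -> np.ndarray:
    """Node radius minus the mean radius within a ±window/2 arclength window."""
    geom = _as_geometry(branch)
    s, r = geom.arclengths, geom.radii
    half = window / 2.0
    excess = np.empty(len(r))
    for i in range(len(r)):
        m = np.abs(s - s[i]) <= half
        excess[i] = r[i] - r[m].mean()
    return excess


def detect_beads(branch, cfg: MorphConfig | None = None) -> list[BeadEvent]:
    """Detect beads/blebs as suppressed maxima of the thickness residual.

    The residual SD is taken over the whole main branch (optionally over
    raw radii via config); maxima are selected sequentially while the
    residual exceeds ``bead_sd_multiplier`` x SD, suppressing neighbors
    within ``bead_nms`` µm.
    """
    cfg = cfg or MorphConfig()
    geom = _as_geometry(branch)
    if len(geom.points) < 3:
        raise ValueError("need at least 3 nodes for bead detection")
    excess = local_thickness_residual(geom, cfg.thickness_window)
    sd = float(np.std(excess if cfg.bead_sd_on_residuals else geom.radii))
    if sd < 1e-9:  # constant radii up to float rounding: no beads
        return []
    s = geom.arclengths
    cand = np.nonzero(excess > cfg.bead_sd_multiplier * sd)[0]
    if len(cand) == 0:
        return []
    order = cand[np.argsort(-excess[cand], kind="stable")]
    picked = _greedy_nms(order, s, cfg.bead_nms)
    events = [
        BeadEvent(
            node_id=int(geom.node_ids[i]),
            excess_radius=float(excess[i]),
            arclength=float(s[i]),
        )
        for i in picked
    ]
    events.sort(key=lambda e: e.arclength)
    _assert_separation([e.arclength for e in events], cfg.bead_nms)
    return events


def spline_curvature(
    branch, smoothing: float = 0.0, n_samples: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """|curvature| of a smoothing cubic B-spline through the main branch.

    Diagnostic only.  The polyline is parameterized by normalized
    arclength; returns ``(arclength grid µm, |curvature| µm⁻¹)`` on a
    uniform grid.
    """
    geom = _as_geometry(branch)
    pts, s = geom.points, geom.arclengths
    if len(pts) < 4:
        raise ValueError("need at least 4 nodes for a cubic spline")
    if geom.length <= 0:
        raise ValueError("degenerate zero-length branch")
    u = s / geom.length
    # collapse duplicate parameter values (coincident nodes)
    keep = np.concatenate([[True], np.diff(u) > 1e-12])
    tck, _ = splprep(pts[keep].T, u=u[keep], s=smoothing, k=3)
    grid = np.linspace(0, 1, n_samples)
    d1 = np.array(splev(grid, tck, der=1)).T
    d2 = np.array(splev(grid, tck, der=2)).T
    speed = np.linalg.norm(d1, axis=1)
    kappa = np.linalg.norm(np.cross(d1, d2), axis=1) / np.maximum(speed, 1e-12) ** 3
    return grid * geom.length, kappa
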