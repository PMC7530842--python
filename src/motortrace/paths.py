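"""Stochastic target-path generation for the tracking task.

The on-screen target follows a continuous chain of cubic Bezier curves,

    B(t) = (1-t)^3 P0 + 3(1-t)^2 t P1 + 3(1-t) t^2 P2 + t^3 P3,   0 <= t <= 1,

whose control points are placed on circles of radius 2.0-2.4 cm around the
previous point, turning by a signed 60-75 degree step per control point.  The
turn direction of each curve is random unless the path approaches a screen
edge, in which case it is forced interior-ward.  Successive curves share an
endpoint (C0) and keep the first control point of the next curve collinear
with the final edge of the previous one (G1), so the chain has no kinks.
The target is then animated along the chain at a constant speed (default
4.25 cm/s) and sampled at 100 Hz via arc-length reparameterization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "PathConfig",
    "BezierSegment",
    "TargetPath",
    "TargetTrace",
    "evaluate_bezier",
    "generate_segment",
    "generate_path",
    "sample_constant_speed",
    "path_to_json",
    "path_from_json",
]

#: usable screen area of a stylus-tablet class device, landscape, cm
DEFAULT_SCREEN_SIZE = (19.7, 14.7)


@dataclass(frozen=True)
class PathConfig:
    """Parameters of the target path and its constant-speed animation.

    Lengths are centimetres, durations seconds, angles degrees.
    """

    n_segments: int = 20
    radius_range: tuple[float, float] = (2.0, 2.4)
    curvature_range: tuple[float, float] = (60.0, 75.0)
    speed: float = 4.25
    sampling_rate: float = 100.0
    n_trials: int = 15
    trial_duration: float = 25.0
    target_radius: float = 0.4
    screen_size: tuple[float, float] = DEFAULT_SCREEN_SIZE
    edge_margin: float = 2.5
    eval_points_per_segment: int = 1000
    max_retries: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if not (self.radius_range[0] <= self.radius_range[1]):
            raise ValueError("radius_range must be non-empty")
        if not (self.curvature_range[0] <= self.curvature_range[1]):
            raise ValueError("curvature_range must be non-empty")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass(frozen=True)
class BezierSegment:
    """One cubic Bezier curve: start P0, control points P1/P2, end P3 (cm)."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    p2: tuple[float, float]
    p3: tuple[float, float]

    @property
    def control_points(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2, self.p3], dtype=float)


@dataclass(frozen=True)
class TargetPath:
    """Ordered chain of Bezier segments sharing endpoints (C0-continuous)."""

    segments: tuple[BezierSegment, ...]
    screen_size: tuple[float, float] = DEFAULT_SCREEN_SIZE

    @property
    def n_segments(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class TargetTrace:
    """Constant-speed sampling of a target path on a uniform time grid."""

    timestamps: np.ndarray
    positions: np.ndarray  # (n, 2), cm
    sampling_rate: float
    speed: float

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0]) if len(self.timestamps) else 0.0

    def __len__(self) -> int:
        return len(self.timestamps)


def evaluate_bezier(seg: BezierSegment, t):
    """Evaluate the cubic Bezier curve in Bernstein form at ``t`` in [0, 1].

    ``t`` may be a scalar or an array; returns an (2,) or (n, 2) array.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0) or np.any(t > 1.0):
        raise ValueError("Bezier parameter t must lie in [0, 1]")
    pts = seg.control_points
    u = 1.0 - t
    b = (
        np.multiply.outer(u**3, pts[0])
        + np.multiply.outer(3.0 * u**2 * t, pts[1])
        + np.multiply.outer(3.0 * u * t**2, pts[2])
        + np.multiply.outer(t**3, pts[3])
    )
    return b


def _inside(point: np.ndarray, screen: tuple[float, float], pad: float = 0.0) -> bool:
    w, h = screen
    return bool(pad <= point[0] <= w - pad and pad <= point[1] <= h - pad)


def _rotate(v: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _candidate(start, d, sign, r1, r2, r3, th2, th3):
    p1 = start + r1 * d
    d1 = _rotate(d, sign * th2)
    p2 = p1 + r2 * d1
    d2 = _rotate(d1 / np.linalg.norm(d1), sign * th3)
    p3 = p2 + r3 * d2
    return p1, p2, p3


def _edge_clearance(points, screen) -> float:
    w, h = screen
    pts = np.atleast_2d(points)
    return float(
        min(pts[:, 0].min(), pts[:, 1].min(), (w - pts[:, 0]).min(), (h - pts[:, 1]).min())
    )


def _forced_turn_sign(start, d, cfg: PathConfig) -> int | None:
    """Interior-ward turn direction when ``start`` is within the edge margin.

    Both turn directions are scored with mid-range radii/curvature and the
    one whose control points keep more clearance from the screen edges wins.
    Returns None when the start is clear of every edge.
    """
    if _edge_clearance(start, cfg.screen_size) >= cfg.edge_margin:
        return None
    r = float(np.mean(cfg.radius_range))
    th = math.radians(float(np.mean(cfg.curvature_range)))
    scores = {}
    for sign in (1, -1):
        pts = np.array(_candidate(start, d, sign, r, r, r, th, th))
        scores[sign] = _edge_clearance(pts, cfg.screen_size)
    return 1 if scores[1] >= scores[-1] else -1


def generate_segment(
    start,
    prev_point,
    bounds: tuple[float, float],
    cfg: PathConfig,
    rng: np.random.Generator,
) -> BezierSegment:
    """Draw one Bezier segment continuing the path from ``start``.

    ``prev_point`` fixes the incoming direction (the previous segment's
    P2 -> P3 edge); P1 is placed collinearly along it so the join is kink
    free.  P2 and P3 are each placed on a circle of radius drawn from
    ``cfg.radius_range`` around the previous point, rotated by a signed
    curvature step drawn from ``cfg.curvature_range``.  The turn sign is
    random away from the screen edges and forced interior-ward within
    ``cfg.edge_margin`` of one.  Draws that put a control point outside the
    screen (or leave no room for the next segment's P1) are rejected and
    resampled up to ``cfg.max_retries`` times.
    """
    start = np.asarray(start, dtype=float)
    prev_point = np.asarray(prev_point, dtype=float)
    if not _inside(start, bounds):
        raise ValueError(f"segment start {tuple(start)} lies outside screen bounds {bounds}")
    d = start - prev_point
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError("prev_point must differ from start to define a direction")
    d = d / nrm

    forced = _forced_turn_sign(start, d, cfg)
    r_lo, r_hi = cfg.radius_range
    th_lo, th_hi = (math.radians(a) for a in cfg.curvature_range)

    for _ in range(cfg.max_retries):
        r1, r2, r3 = rng.uniform(r_lo, r_hi, size=3)
        th2, th3 = rng.uniform(th_lo, th_hi, size=2)
        sign = forced if forced is not None else (1 if rng.random() < 0.5 else -1)
        p1, p2, p3 = _candidate(start, d, sign, r1, r2, r3, th2, th3)
        if not (_inside(p1, bounds) and _inside(p2, bounds) and _inside(p3, bounds)):
            continue
        # leave room for the next segment: its collinear P1 at any admissible
        # radius, and at least one turn direction for its P2 at the sharpest
        # admissible turn
        d_out = (p3 - p2) / np.linalg.norm(p3 - p2)
        if not (_inside(p3 + r_lo * d_out, bounds) and _inside(p3 + r_hi * d_out, bounds)):
            continue
        next_p1 = p3 + r_hi * d_out
        if not any(
            _inside(next_p1 + r_lo * _rotate(d_out, s * th_hi), bounds) for s in (1, -1)
        ):
            continue
        return BezierSegment(tuple(start), tuple(p1), tuple(p2), tuple(p3))
    raise RuntimeError(
        f"could not place a segment satisfying the screen-bound constraint "
        f"after {cfg.max_retries} retries (start={tuple(start)})"
    )


def generate_path(cfg: PathConfig, rng: np.random.Generator) -> TargetPath:
    """Chain ``cfg.n_segments`` segments into one continuous path.

    The path starts at the screen centre heading in a random direction;
    each subsequent segment starts exactly at the previous endpoint (C0)
    and continues its final edge direction (G1).  If a segment cannot be
    placed (the chain cornered itself), the previous segment is discarded
    and redrawn, up to a bounded backtracking budget.
    """
    screen = cfg.screen_size
    centre = np.array([screen[0] / 2.0, screen[1] / 2.0])
    angle = rng.uniform(0.0, 2.0 * math.pi)
    init_prev = centre - np.array([math.cos(angle), math.sin(angle)])
    segments: list[BezierSegment] = []
    backtracks = 0
    while len(segments) < cfg.n_segments:
        if segments:
            start = np.asarray(segments[-1].p3, dtype=float)
            prev_point = np.asarray(segments[-1].p2, dtype=float)
        else:
            start, prev_point = centre, init_prev
        try:
            segments.append(generate_segment(start, prev_point, screen, cfg, rng))
        except RuntimeError:
            backtracks += 1
            if backtracks > cfg.max_retries or not segments:
                raise
            segments.pop()  # undo the turn that cornered the chain
    return TargetPath(tuple(segments), screen)


def _dense_polyline(path: TargetPath, points_per_segment: int) -> tuple[np.ndarray, np.ndarray]:
    """Dense evaluation of the whole chain with cumulative chord length."""
    chunks = []
    for k, seg in enumerate(path.segments):
        t = np.linspace(0.0, 1.0, points_per_segment + 1)
        pts = evaluate_bezier(seg, t)
        chunks.append(pts if k == 0 else pts[1:])  # drop duplicated join point
    pts = np.concatenate(chunks, axis=0)
    step = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(step)])
    return pts, s


def sample_constant_speed(path: TargetPath, cfg: PathConfig) -> TargetTrace:
    """Sample the path at ``cfg.sampling_rate`` Hz moving at ``cfg.speed`` cm/s.

    Arc length is approximated by cumulative chord length on a dense
    per-segment grid; sample positions are linearly interpolated at equal
    arc-length increments of speed / sampling_rate.
    """
    pts, s = _dense_polyline(path, cfg.eval_points_per_segment)
    total = s[-1]
    ds = cfg.speed / cfg.sampling_rate
    if total < ds:
        raise ValueError(
            f"path arc length {total:.4g} cm is shorter than one sample interval ({ds:.4g} cm)"
        )
    n = int(math.floor(total / ds * (1.0 + 1e-9))) + 1
    s_grid = np.arange(n) * ds
    x = np.interp(s_grid, s, pts[:, 0])
    y = np.interp(s_grid, s, pts[:, 1])
    t = np.arange(n) / cfg.sampling_rate
    return TargetTrace(t, np.column_stack([x, y]), cfg.sampling_rate, cfg.speed)


def path_to_json(path: TargetPath, cfg: PathConfig | None = None, seed: int | None = None) -> str:
    doc = {
        "format_version": "1",
        "screen_size": list(path.screen_size),
        "segments": [
            {"p0": list(s.p0), "p1": list(s.p1), "p2": list(s.p2), "p3": list(s.p3)}
            for s in path.segments
        ],
    }
    if cfg is not None:
        doc["config"] = asdict(cfg)
    if seed is not None:
        doc["seed"] = seed
    return json.dumps(doc, indent=2)


def path_from_json(text: str) -> TargetPath:
    doc = json.loads(text)
    segs = tuple(
        BezierSegment(tuple(s["p0"]), tuple(s["p1"]), tuple(s["p2"]), tuple(s["p3"]))
        for s in doc["segments"]
    )
    return TargetPath(segs, tuple(doc.get("screen_size", DEFAULT_SCREEN_SIZE)))
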