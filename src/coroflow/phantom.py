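"""Synthetic cine angiography phantom with known ground truth.

Generates a branching coronary-artery-like tree, advances a contrast-dye
front through it at a known speed, deforms the geometry with a
quasi-periodic cardiac motion model, and renders 8-bit X-ray-like frames
(dark vessels on a brighter background with organ shadows, a static
catheter, and sensor noise). Every frame comes with a ground-truth dye mask
and the true covered centerline length, so each downstream pipeline stage
can be validated without patient data.

The dye kinematics realize mass conservation through branchings: every
bifurcation doubles the branch count and halves the front speed
(``v_child = v_parent * n_parent / n_child``), so under the constant-area
assumption the *summed* covered centerline length grows at exactly the
injected front speed until the tree is full.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.interpolate import RectBivariateSpline

from .core import AngioSequence, DEFAULT_FPS, DEFAULT_PIXEL_SPACING_MM

__all__ = [
    "VesselTree",
    "MotionModel",
    "PhantomTruth",
    "generate_tree",
    "render_sequence",
    "write_truth",
    "read_truth",
]

# Intensity model (8-bit): bright background, low-frequency organ shadows,
# dye-filled vessels darkened well below the catheter.
BACKGROUND_LEVEL = 200.0
SHADOW_MAX_DEPTH = 30.0
VESSEL_DEPTH = 80.0
CATHETER_DEPTH = 60.0

#: Default vessel half-width in pixels (constant along the tree so the
#: constant-cross-section assumption holds exactly). 3.5 px at 0.2 mm/px is
#: a 1.4 mm vessel, consistent with mid coronary arteries and with the
#: expected per-frame dye growth of several hundred pixels.
DEFAULT_HALF_WIDTH_PX = 3.5
CATHETER_HALF_WIDTH_PX = 3.0

_LENGTH_DECAY = 0.7          # generation-wise segment length decay
_ROOT_LENGTH_FRAC = 0.30     # root segment length as fraction of image size
_BRANCH_ANGLE_DEG = (25.0, 40.0)
_BORDER_MARGIN = 10.0        # px kept clear of the image border


@dataclass
class Segment:
    """One centerline polyline sampled at ~1 px arc-length steps."""

    points: np.ndarray          # (n, 2) array of (row, col)
    parent: int                 # parent segment index, -1 for the root
    generation: int

    @property
    def length_px(self) -> float:
        return float(len(self.points) - 1)


@dataclass
class VesselTree:
    """Branching centerline tree plus the catheter path leading to its root."""

    segments: list[Segment]
    widths: list[float]                 # half-width in px per segment
    root: tuple[float, float]           # catheter-tip coordinate (row, col)
    pixel_spacing_mm: float
    image_size: int
    catheter_points: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def total_length_mm(self) -> float:
        return sum(s.length_px for s in self.segments) * self.pixel_spacing_mm

    @property
    def generations(self) -> int:
        return max(s.generation for s in self.segments) + 1

    def branch_counts(self) -> list[int]:
        """Number of segments per generation; doubles each generation."""
        counts = [0] * self.generations
        for s in self.segments:
            counts[s.generation] += 1
        return counts


@dataclass
class MotionModel:
    """Quasi-periodic cardiac deformation plus breathing drift.

    The cardiac component is a global cyclic affine (scale
    ``1 + a*sin(2*pi*f*t)`` and rotation ``a*sin`` about the image centre)
    composed with a cyclic B-spline warp sharing the same phase; breathing
    is a slow translation drift.
    """

    cardiac_frequency_hz: float = 1.2
    affine_amplitude: float = 0.03
    warp_amplitude_px: float = 4.0
    warp_grid_spacing_px: float = 32.0
    drift_px_per_frame: float = 0.1

    def __post_init__(self) -> None:
        if self.cardiac_frequency_hz <= 0:
            raise ValueError("cardiac frequency must be positive")
        if min(self.affine_amplitude, self.warp_amplitude_px,
               self.drift_px_per_frame) < 0:
            raise ValueError("motion amplitudes must be non-negative")
        if self.warp_grid_spacing_px < 4:
            raise ValueError("warp grid spacing must be at least 4 px")

    @classmethod
    def still(cls) -> "MotionModel":
        """Motion-free model (all amplitudes zero)."""
        return cls(affine_amplitude=0.0, warp_amplitude_px=0.0,
                   drift_px_per_frame=0.0)


@dataclass
class PhantomTruth:
    """Per-frame ground truth emitted alongside a rendered sequence."""

    truth_masks: np.ndarray             # (n_frames, rows, cols) bool
    truth_skeleton_length_mm: np.ndarray
    true_velocity_m_per_s: float
    injection_start_frame: int
    full_propagation_frame: int
    catheter_mask: np.ndarray = None    # type: ignore[assignment]
    total_length_mm: float = float("nan")


def _rotate(vec: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])


def _trace(start: np.ndarray, heading: float, n_steps: int, curvature: float,
           size: int, rng: np.random.Generator) -> np.ndarray:
    """Walk ``n_steps`` unit steps with gentle curvature, steering away
    from the image border so the polyline stays inside the margin."""
    pts = np.empty((n_steps + 1, 2))
    pts[0] = start
    th = heading
    centre = np.array([size / 2.0, size / 2.0])
    for i in range(n_steps):
        step = np.array([np.sin(th), np.cos(th)])
        nxt = pts[i] + step
        # steer toward the centre when the lookahead approaches the border
        look = pts[i] + 12.0 * step
        if (look.min() < _BORDER_MARGIN) or (look.max() > size - _BORDER_MARGIN):
            to_centre = centre - pts[i]
            want = np.arctan2(to_centre[0], to_centre[1])
            dth = (want - th + np.pi) % (2 * np.pi) - np.pi
            th += np.clip(dth, -0.12, 0.12)
        else:
            th += curvature
        pts[i + 1] = pts[i] + np.array([np.sin(th), np.cos(th)])
    return pts


def generate_tree(seed: int, generations: int, image_size: int,
                  pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM,
                  half_width_px: float = DEFAULT_HALF_WIDTH_PX,
                  tapering: float = 1.0) -> VesselTree:
    """Generate a seeded branching vessel tree inside the image bounds.

    Each generation doubles the branch count; generation-``g`` segments are
    ``0.7**g`` times the root length, and sibling branches leave their
    parent at symmetric random angles of 25-40 degrees. Segments are gently
    curved quadratic-like arcs sampled at 1-px steps.

    ``tapering`` < 1 multiplies the half-width by ``tapering**g`` per
    generation, for probing the constant-area assumption; the default 1.0
    keeps the width constant along the whole tree.
    """
    if generations < 1:
        raise ValueError("need at least one generation")
    if image_size < 128:
        raise ValueError("image_size must be at least 128 px")
    rng = np.random.default_rng(seed)

    root_len = _ROOT_LENGTH_FRAC * image_size
    # reject geometries that cannot fit: the worst-case radial extent of the
    # tree must stay inside the image diagonal
    extent = root_len * (1 - _LENGTH_DECAY ** generations) / (1 - _LENGTH_DECAY)
    if extent > 1.35 * image_size:
        raise ValueError(
            f"{generations} generations do not fit in a {image_size} px image")

    start = np.array([0.16 * image_size, 0.16 * image_size])
    heading = np.pi / 4 + rng.uniform(-0.15, 0.15)  # toward the far corner

    segments: list[Segment] = []
    widths: list[float] = []
    frontier: list[tuple[int, np.ndarray, float]] = []  # (index, end, heading)

    n_steps = int(round(root_len))
    pts = _trace(start, heading, n_steps, rng.uniform(-0.004, 0.004),
                 image_size, rng)
    segments.append(Segment(pts, parent=-1, generation=0))
    widths.append(half_width_px)
    end_heading = np.arctan2(*(pts[-1] - pts[-2]))
    frontier.append((0, pts[-1], end_heading))

    for g in range(1, generations):
        length = root_len * _LENGTH_DECAY ** g
        new_frontier = []
        for parent_idx, origin, th in frontier:
            ang = np.deg2rad(rng.uniform(*_BRANCH_ANGLE_DEG))
            for sign in (+1.0, -1.0):
                child_heading = th + sign * ang
                pts = _trace(origin, child_heading, int(round(length)),
                             rng.uniform(-0.008, 0.008), image_size, rng)
                segments.append(Segment(pts, parent=parent_idx, generation=g))
                widths.append(half_width_px * tapering ** g)
                new_frontier.append(
                    (len(segments) - 1, pts[-1], np.arctan2(*(pts[-1] - pts[-2]))))
        frontier = new_frontier

    all_pts = np.vstack([s.points for s in segments])
    if all_pts.min() < 0 or all_pts.max() > image_size - 1:
        raise ValueError("generated tree leaves the image bounds; "
                         "increase image_size or reduce generations")

    # catheter: straight-ish path from the image border to the tree root
    cath_dir = np.array([np.sin(heading), np.cos(heading)])
    t_edge = min(start[0] / max(cath_dir[0], 1e-9),
                 start[1] / max(cath_dir[1], 1e-9))
    entry = start - cath_dir * t_edge
    n = int(np.ceil(t_edge))
    cath = entry[None, :] + np.linspace(0, t_edge, n + 1)[:, None] * cath_dir[None, :]

    return VesselTree(segments=segments, widths=widths,
                      root=(float(start[0]), float(start[1])),
                      pixel_spacing_mm=pixel_spacing_mm,
                      image_size=image_size, catheter_points=cath)


def _fill_schedule(tree: VesselTree, speed_px_s: float):
    """Per-segment (start time [s], speed [px/s]) of the dye front.

    The root fills at the injected speed; each bifurcation halves the speed
    (branch count doubles, total cross-section is conserved). A child starts
    when its parent finishes.
    """
    start_time = np.zeros(len(tree.segments))
    speeds = np.array([speed_px_s / 2 ** s.generation for s in tree.segments])
    finish = np.zeros(len(tree.segments))
    for i, seg in enumerate(tree.segments):
        t0 = 0.0 if seg.parent < 0 else finish[seg.parent]
        start_time[i] = t0
        finish[i] = t0 + seg.length_px / speeds[i]
    return start_time, speeds, float(finish.max())


def _stamp_disks(canvas: np.ndarray, points: np.ndarray, radius: float) -> None:
    """Set ``canvas`` True inside a disk of ``radius`` around each point."""
    if len(points) == 0:
        return
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dy ** 2 + dx ** 2 <= radius ** 2
    offs = np.stack([dy[keep], dx[keep]], axis=1)
    pix = np.round(points).astype(int)[:, None, :] + offs[None, :, :]
    pix = pix.reshape(-1, 2)
    np.clip(pix, 0, np.array(canvas.shape) - 1, out=pix)
    canvas[pix[:, 0], pix[:, 1]] = True


class _Warp:
    """Frame-time-dependent cardiac + breathing displacement of points."""

    def __init__(self, motion: MotionModel, size: int, seed: int):
        rng = np.random.default_rng(seed)
        self.motion = motion
        self.size = size
        self.centre = np.array([size / 2.0, size / 2.0])
        spacing = motion.warp_grid_spacing_px
        n = max(int(np.ceil(size / spacing)) + 1, 4)
        grid = np.linspace(0, size - 1, n)
        # fixed random control-point displacement pattern, unit RMS amplitude
        u = rng.normal(size=(2, n, n))
        u /= max(np.sqrt(np.mean(u ** 2)), 1e-12)
        self._splines = [RectBivariateSpline(grid, grid, u[i], kx=3, ky=3)
                         for i in range(2)]
        self.drift_dir = rng.normal(size=2)
        self.drift_dir /= np.linalg.norm(self.drift_dir)

    def __call__(self, points: np.ndarray, frame: int, fps: float) -> np.ndarray:
        m = self.motion
        t = frame / fps
        phase = np.sin(2 * np.pi * m.cardiac_frequency_hz * t)
        out = points.astype(float)
        if m.affine_amplitude > 0:
            scale = 1.0 + m.affine_amplitude * phase
            ang = m.affine_amplitude * phase
            c, s = np.cos(ang), np.sin(ang)
            rel = out - self.centre
            rot = np.stack([c * rel[:, 0] - s * rel[:, 1],
                            s * rel[:, 0] + c * rel[:, 1]], axis=1)
            out = self.centre + scale * rot
        if m.warp_amplitude_px > 0:
            amp = m.warp_amplitude_px * phase
            disp = np.stack(
                [sp(out[:, 0], out[:, 1], grid=False) for sp in self._splines],
                axis=1)
            out = out + amp * disp
        if m.drift_px_per_frame > 0:
            out = out + m.drift_px_per_frame * frame * self.drift_dir
        return out


def render_sequence(tree: VesselTree, true_velocity_m_per_s: float,
                    motion: MotionModel, n_frames: int,
                    fps: float = DEFAULT_FPS, noise_sd: float = 0.0,
                    seed: int = 0, injection_start_frame: int = 8,
                    foreshorten: float = 1.0,
                    ) -> tuple[AngioSequence, PhantomTruth]:
    """Render a cine sequence of the dye front advancing through ``tree``.

    Frames before ``injection_start_frame`` show the catheter only. The
    truth masks are the pre-noise dye-covered tubes (warped geometry); the
    truth skeleton length is the covered centerline length in the tree's
    own (unwarped) geometry, which saturates at ``tree.total_length_mm``.

    ``foreshorten`` < 1 compresses the displayed geometry along the image
    rows about the root, emulating vessels tilted away from the projection
    plane: the dye still travels its true 3D path length, but the projected
    skeleton shortens.
    """
    if n_frames < 10:
        raise ValueError("need at least 10 frames")
    if fps <= 0 or true_velocity_m_per_s <= 0:
        raise ValueError("fps and velocity must be positive")
    if not 0 < foreshorten <= 1:
        raise ValueError("foreshorten must be in (0, 1]")

    spacing = tree.pixel_spacing_mm
    speed_px_s = true_velocity_m_per_s * 1000.0 / spacing
    start_time, speeds, fill_time_s = _fill_schedule(tree, speed_px_s)
    if fill_time_s * fps < 3:
        raise ValueError("velocity too large: the tree fills in fewer than "
                         "3 frames, timing would be undetectable")
    full_frame = injection_start_frame + int(np.ceil(fill_time_s * fps))
    if full_frame >= n_frames:
        raise ValueError("sequence too short: full propagation at frame "
                         f"{full_frame} >= n_frames={n_frames}")

    size = tree.image_size
    rng = np.random.default_rng(seed)
    warp = _Warp(motion, size, seed=seed + 1)

    # static organ shadows: 2-4 seeded low-frequency Gaussian blobs
    yy, xx = np.mgrid[:size, :size].astype(float)
    shadow = np.zeros((size, size))
    for _ in range(rng.integers(2, 5)):
        cy, cx = rng.uniform(0, size, 2)
        sig = rng.uniform(0.15, 0.35) * size
        depth = rng.uniform(0.4, 1.0) * SHADOW_MAX_DEPTH
        shadow += depth * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig ** 2))
    shadow = np.clip(shadow, 0, SHADOW_MAX_DEPTH)

    root = np.asarray(tree.root)

    def project(pts: np.ndarray) -> np.ndarray:
        if foreshorten >= 1.0:
            return pts
        out = pts.copy()
        out[:, 0] = root[0] + foreshorten * (out[:, 0] - root[0])
        return out

    cath_mask = np.zeros((size, size), dtype=bool)
    _stamp_disks(cath_mask, project(tree.catheter_points), CATHETER_HALF_WIDTH_PX)

    frames = np.empty((n_frames, size, size), dtype=np.float64)
    truth_masks = np.zeros((n_frames, size, size), dtype=bool)
    truth_len_mm = np.zeros(n_frames)

    for k in range(n_frames):
        tau = (k - injection_start_frame) / fps  # seconds since injection
        dye = np.zeros((size, size), dtype=bool)
        covered_px = 0.0
        if tau > 0:
            pts_list = []
            for i, seg in enumerate(tree.segments):
                n_cov = int(np.floor(np.clip((tau - start_time[i]) * speeds[i],
                                             0, seg.length_px)))
                covered_px += min((tau - start_time[i]) * speeds[i]
                                  if tau > start_time[i] else 0.0, seg.length_px)
                if n_cov > 0:
                    pts_list.append(seg.points[:n_cov + 1])
            if pts_list:
                pts = project(np.vstack(pts_list))
                pts = warp(pts, k, fps)
                _stamp_disks(dye, pts, tree.widths[0])
        truth_masks[k] = dye
        truth_len_mm[k] = covered_px * spacing

        img = BACKGROUND_LEVEL - shadow
        img[cath_mask] -= CATHETER_DEPTH
        img[dye] = BACKGROUND_LEVEL - shadow[dye] - VESSEL_DEPTH
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames[k] = np.clip(np.round(img), 0, 255)

    seq = AngioSequence(frames, fps=fps, pixel_spacing_mm=spacing)
    truth = PhantomTruth(
        truth_masks=truth_masks,
        truth_skeleton_length_mm=truth_len_mm,
        true_velocity_m_per_s=true_velocity_m_per_s,
        injection_start_frame=injection_start_frame,
        full_propagation_frame=full_frame,
        catheter_mask=cath_mask,
        total_length_mm=tree.total_length_mm,
    )
    return seq, truth


def write_truth(truth: PhantomTruth, path) -> None:
    """Write truth masks (multi-page TIFF) plus a JSON scalar sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path / "truth_masks.tif",
                     truth.truth_masks.astype(np.uint8) * 255,
                     photometric="minisblack")
    tifffile.imwrite(path / "catheter_mask.tif",
                     truth.catheter_mask.astype(np.uint8) * 255,
                     photometric="minisblack")
    sidecar = {
        "truth_skeleton_length_mm": truth.truth_skeleton_length_mm.tolist(),
        "true_velocity_m_per_s": truth.true_velocity_m_per_s,
        "injection_start_frame": truth.injection_start_frame,
        "full_propagation_frame": truth.full_propagation_frame,
        "total_length_mm": truth.total_length_mm,
    }
    (path / "truth.json").write_text(json.dumps(sidecar, indent=2))


def read_truth(path) -> PhantomTruth:
    """Read back what :func:`write_truth` wrote (lossless round-trip)."""
    path = Path(path)
    masks = tifffile.imread(path / "truth_masks.tif") > 0
    if masks.ndim == 2:
        masks = masks[None]
    cath = tifffile.imread(path / "catheter_mask.tif") > 0
    meta = json.loads((path / "truth.json").read_text())
    return PhantomTruth(
        truth_masks=masks,
        truth_skeleton_length_mm=np.array(meta["truth_skeleton_length_mm"]),
        true_velocity_m_per_s=meta["true_velocity_m_per_s"],
        injection_start_frame=meta["injection_start_frame"],
        full_propagation_frame=meta["full_propagation_frame"],
        catheter_mask=cath,
        total_length_mm=meta["total_length_mm"],
    )
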