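"""Pronucleus trajectory extraction by sparse pyramidal Lucas-Kanade flow.

The two pronuclei (PNs) of a zygote are tracked from their appearance (tPNa)
to their fading (tPNf) in grayscale time-lapse stacks.  Fifteen mutually
non-adjacent pixels are seeded inside each PN disc at the starting frame and
followed through consecutive frames with an iterative, pyramidal
Lucas-Kanade solver using a 15x15 pixel window; the PN position per frame is
the mean of the surviving tracks.  Tracking is run both forward (tPNa to
tPNf) and in reverse, and positions are reported in the embryo frame of
reference (the per-frame ooplasm center is subtracted), so that the derived
features are invariant to global scene translation.

The solver is translation-only Lucas-Kanade: for a window W around point p
with spatial gradients (Ix, Iy), the flow v solves G v = b with
G = sum_W [Ix^2, IxIy; IxIy, Iy^2] and b = sum_W dI * (Ix, Iy), iterated
with bilinear resampling of the target frame.  Windows whose minimum
eigenvalue of G (per pixel) falls below a threshold, or whose track leaves
the frame, are dropped; a trajectory with fewer than 8 surviving tracks is
marked unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional

import numpy as np
from scipy import ndimage

from .catalog import DIRECTIONS, DIST_STATS, PATH_STATS, PN_DYNAMICS_NAMES, PN_SIDES, SEP_STATS

__all__ = [
    "PNTrajectory",
    "select_seed_points",
    "lk_track_points",
    "track_pn",
    "classify_trajectory",
    "pn_dynamics_features",
    "ooplasm_centroid",
]

MIN_RELIABLE_TRACKS = 8


def _map(img: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    flat = ndimage.map_coordinates(img, [ys.ravel(), xs.ravel()], order=1, mode="nearest")
    return flat.reshape(ys.shape)


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [np.asarray(img, dtype=float)]
    for _ in range(levels - 1):
        if min(pyr[-1].shape) < 16:
            break
        pyr.append(ndimage.gaussian_filter(pyr[-1], 1.0)[::2, ::2])
    return pyr


def _lk_level(I: np.ndarray, J: np.ndarray, pts: np.ndarray, guess: np.ndarray,
              win_radius: int, n_iter: int, tol: float, min_eig: float,
              ) -> tuple[np.ndarray, np.ndarray]:
    """One pyramid level; returns (flow, ok) for all points at this scale."""
    Iy, Ix = np.gradient(I)
    offs = np.arange(-win_radius, win_radius + 1, dtype=float)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    px = pts[:, 0][:, None, None] + ox
    py = pts[:, 1][:, None, None] + oy
    patch_i = _map(I, py, px)
    gx = _map(Ix, py, px)
    gy = _map(Iy, py, px)
    gxx = (gx * gx).sum((1, 2))
    gxy = (gx * gy).sum((1, 2))
    gyy = (gy * gy).sum((1, 2))
    tr, det = gxx + gyy, gxx * gyy - gxy ** 2
    eig_min = 0.5 * (tr - np.sqrt(np.maximum(tr ** 2 - 4 * det, 0.0)))
    n_pix = (2 * win_radius + 1) ** 2
    ok = eig_min / n_pix >= min_eig
    safe_det = np.where(det > 1e-12, det, np.inf)
    v = guess.astype(float).copy()
    for _ in range(n_iter):
        patch_j = _map(J, py + v[:, 1][:, None, None], px + v[:, 0][:, None, None])
        di = patch_i - patch_j
        bx = (di * gx).sum((1, 2))
        by = (di * gy).sum((1, 2))
        dx = (gyy * bx - gxy * by) / safe_det
        dy = (-gxy * bx + gxx * by) / safe_det
        v[:, 0] += dx
        v[:, 1] += dy
        if max(np.abs(dx).max(initial=0.0), np.abs(dy).max(initial=0.0)) < tol:
            break
    return v, ok


def lk_track_points(prev: np.ndarray, curr: np.ndarray, pts: np.ndarray,
                    win_radius: int = 7, n_levels: int = 2, n_iter: int = 20,
                    tol: float = 0.01, min_eig: float = 5.0,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Track points (x, y) from ``prev`` to ``curr``; returns (new_pts, ok)."""
    pts = np.asarray(pts, dtype=float)
    pyr_i = _pyramid(prev, n_levels)
    pyr_j = _pyramid(curr, n_levels)
    g = np.zeros_like(pts)
    ok = np.ones(len(pts), dtype=bool)
    for level in reversed(range(len(pyr_i))):
        scale = 2.0 ** level
        v, lvl_ok = _lk_level(pyr_i[level], pyr_j[level], pts / scale, g / scale,
                              win_radius, n_iter, tol, min_eig)
        g = scale * v
        if level == 0:
            ok &= lvl_ok
    new = pts + g
    h, w = np.asarray(curr).shape
    ok &= np.isfinite(new).all(axis=1)
    new_safe = np.where(np.isfinite(new), new, -1.0)
    ok &= (new_safe[:, 0] >= 0) & (new_safe[:, 0] <= w - 1)
    ok &= (new_safe[:, 1] >= 0) & (new_safe[:, 1] <= h - 1)
    return new, ok


def select_seed_points(center: tuple[float, float], radius: float, n: int = 15,
                       min_spacing: float = 2.0, seed: int = 0,
                       margin: float = 2.0) -> np.ndarray:
    """Sample ``n`` mutually non-adjacent pixels inside a PN disc.

    Uniform rejection sampling inside the disc (shrunk by ``margin``) with a
    minimum pairwise spacing, under a fixed seed for reproducibility.
    """
    rng = np.random.default_rng(seed)
    r_eff = max(radius - margin, 1.0)
    pts: list[np.ndarray] = []
    for _ in range(20000):
        if len(pts) == n:
            break
        u = rng.uniform(-r_eff, r_eff, size=2)
        if u[0] ** 2 + u[1] ** 2 > r_eff ** 2:
            continue
        cand = np.asarray(center, float) + u
        if all(np.hypot(*(cand - p)) >= min_spacing for p in pts):
            pts.append(cand)
    if len(pts) < n:  # dense disc fallback: accept closer points
        while len(pts) < n:
            u = rng.uniform(-r_eff, r_eff, size=2)
            if u[0] ** 2 + u[1] ** 2 <= r_eff ** 2:
                pts.append(np.asarray(center, float) + u)
    return np.asarray(pts)


def ooplasm_centroid(frame: np.ndarray) -> np.ndarray:
    """Intensity centroid of the foreground (ooplasm) pixels, as (x, y)."""
    img = np.asarray(frame, dtype=float)
    thresh = 0.5 * (img.min() + img.max())
    mask = img > thresh
    if not mask.any():
        return np.array([(img.shape[1] - 1) / 2.0, (img.shape[0] - 1) / 2.0])
    ys, xs = np.nonzero(mask)
    return np.array([xs.mean(), ys.mean()])


@dataclass
class PNTrajectory:
    """Time-ordered positions of one PN in the embryo frame of reference."""

    pn: Literal["small", "large"]
    direction: Literal["fwd", "rev"]
    positions: np.ndarray                  # (N, 2) relative to ooplasm center
    times: np.ndarray                      # hours; increasing fwd, decreasing rev
    n_tracks: int = 15
    reliable: bool = True
    absolute_positions: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.positions) != len(self.times):
            raise ValueError("positions and times length mismatch")
        dt = np.diff(self.times)
        if self.direction == "fwd" and not (dt > 0).all():
            raise ValueError("forward trajectory requires strictly increasing times")
        if self.direction == "rev" and not (dt < 0).all():
            raise ValueError("reverse trajectory requires strictly decreasing times")

    @property
    def steps(self) -> np.ndarray:
        """(N-1) per-step displacements r_i, pixels."""
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    @property
    def velocities(self) -> np.ndarray:
        """(N-1) per-step speeds, pixels/hour."""
        return self.steps / np.abs(np.diff(self.times))


def track_pn(frames: np.ndarray, pn_center: tuple[float, float], pn_radius: float,
             direction: Literal["fwd", "rev"] = "fwd", *,
             frame_interval_min: float = 30.0, t_start_h: float = 0.0,
             ooplasm_centers: Optional[np.ndarray] = None,
             pn: Literal["small", "large"] = "small",
             n_points: int = 15, win_radius: int = 7, seed: int = 0) -> PNTrajectory:
    """Track one PN through an image stack.

    ``pn_center``/``pn_radius`` describe the seed disc at the starting frame
    — the first frame for forward tracking, the last for reverse.
    ``ooplasm_centers`` (T, 2), if given (e.g. synthetic ground truth),
    defines the embryo frame of reference; otherwise the per-frame intensity
    centroid is used.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (T, H, W) stack with at least 2 frames")
    n_frames = frames.shape[0]
    order = np.arange(n_frames) if direction == "fwd" else np.arange(n_frames)[::-1]
    if ooplasm_centers is None:
        centers = np.asarray([ooplasm_centroid(frames[i]) for i in order])
    else:
        centers = np.asarray(ooplasm_centers, dtype=float)[order]

    pts = select_seed_points(pn_center, pn_radius, n=n_points, seed=seed)
    alive = np.ones(len(pts), dtype=bool)
    all_pts = np.empty((n_frames, len(pts), 2))
    all_pts[0] = pts
    for k in range(1, n_frames):
        new, ok = lk_track_points(frames[order[k - 1]], frames[order[k]],
                                  all_pts[k - 1], win_radius=win_radius)
        alive &= ok
        all_pts[k] = new
    n_alive = int(alive.sum())
    if n_alive > 0:
        mean_pos = all_pts[:, alive, :].mean(axis=1)
    else:
        mean_pos = np.full((n_frames, 2), np.nan)
    rel = mean_pos - centers
    dt_h = frame_interval_min / 60.0
    times = t_start_h + dt_h * np.arange(n_frames)
    if direction == "rev":
        times = t_start_h + dt_h * (n_frames - 1) - dt_h * np.arange(n_frames)
    return PNTrajectory(pn=pn, direction=direction, positions=rel, times=times,
                        n_tracks=n_alive, reliable=n_alive >= MIN_RELIABLE_TRACKS,
                        absolute_positions=mean_pos)


def classify_trajectory(traj: PNTrajectory, pn_radius: float,
                        theta_s: float = 0.5, theta_l: float = 0.8) -> str:
    """Classify a trajectory as ``stationary``, ``linear`` or ``curved``.

    Stationary: end-to-end distance below ``theta_s * pn_radius``.  Otherwise
    linear when straightness (end-to-end / contour length) is at least
    ``theta_l``; curved below that.
    """
    if len(traj.positions) < 3:
        raise ValueError("need at least 3 positions to classify")
    e2e = float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))
    if e2e < theta_s * pn_radius:
        return "stationary"
    path = float(traj.steps.sum())
    straightness = e2e / path if path > 0 else 1.0
    return "linear" if straightness >= theta_l else "curved"


# --------------------------------------------------------------- features

def _series_stats(x: np.ndarray, stats: tuple[str, ...]) -> dict[str, float]:
    out = {}
    if x is None or len(x) == 0 or not np.isfinite(x).all():
        return {s: np.nan for s in stats}
    fns = {
        "min": np.min, "max": np.max, "mean": np.mean, "median": np.median,
        "std": np.std, "first": lambda a: a[0], "last": lambda a: a[-1],
        "total": np.sum, "range": np.ptp,
        "iqr": lambda a: np.percentile(a, 75) - np.percentile(a, 25),
    }
    for s in stats:
        out[s] = float(fns[s](x))
    return out


def pn_dynamics_features(trajs: Mapping[tuple[str, str], PNTrajectory],
                         ooplasm_radius: float) -> dict[str, float]:
    """The 162 PN-dynamics features from per-(PN, direction) trajectories.

    ``trajs`` maps ("small"|"large", "fwd"|"rev") to trajectories; a missing
    direction yields NaN for all its features.  Includes f5 (ratio of the
    maximal step sizes, large/small, forward) and f6 (absolute difference of
    PN-to-embryo-center distances at the tPNf frame).
    """
    out: dict[str, float] = {n: np.nan for n in PN_DYNAMICS_NAMES}

    for qty in ("step", "velocity"):
        for pn in PN_SIDES:
            for d in DIRECTIONS:
                t = trajs.get((pn, d))
                x = (t.steps if qty == "step" else t.velocities) if t is not None else None
                for s, v in _series_stats(x, PATH_STATS).items():
                    out[f"pn_{qty}_{s}_{pn}_{d}"] = v
        for d in DIRECTIONS:
            ts, tl = trajs.get(("small", d)), trajs.get(("large", d))
            if ts is None or tl is None or len(ts.steps) == 0 or len(tl.steps) == 0:
                continue
            xs = ts.steps if qty == "step" else ts.velocities
            xl = tl.steps if qty == "step" else tl.velocities
            if not (np.isfinite(xs).all() and np.isfinite(xl).all()):
                continue
            max_s = float(xs.max())
            # small PN that never moves -> ratio undefined (flagged as NaN)
            out[f"pn_{qty}_max_ratio_{d}"] = abs(xl.max() / max_s) if max_s > 0 else np.nan
            out[f"pn_{qty}_min_absdiff_{d}"] = abs(float(xl.min()) - float(xs.min()))

    for d in DIRECTIONS:
        ts, tl = trajs.get(("small", d)), trajs.get(("large", d))
        if ts is None or tl is None or len(ts.positions) != len(tl.positions):
            continue
        sep = np.linalg.norm(tl.positions - ts.positions, axis=1)
        for s, v in _series_stats(sep, SEP_STATS).items():
            out[f"pn_sep_{s}_{d}"] = v

    for scale, denom in (("raw", 1.0), ("norm", ooplasm_radius)):
        for pn in PN_SIDES:
            for d in DIRECTIONS:
                t = trajs.get((pn, d))
                x = np.linalg.norm(t.positions, axis=1) / denom if t is not None else None
                for s, v in _series_stats(x, DIST_STATS).items():
                    out[f"pn_centerdist_{s}_{pn}_{d}_{scale}"] = v
        for d in DIRECTIONS:
            ts, tl = trajs.get(("small", d)), trajs.get(("large", d))
            if ts is None or tl is None or len(ts.positions) != len(tl.positions):
                continue
            ds = np.linalg.norm(ts.positions, axis=1) / denom
            dl = np.linalg.norm(tl.positions, axis=1) / denom
            if not (np.isfinite(ds).all() and np.isfinite(dl).all()):
                continue
            diff = np.abs(dl - ds)
            # tPNf is the last forward frame and the first reverse frame
            idx_tpnf = -1 if d == "fwd" else 0
            out[f"pn_centerdist_absdiff_tpnf_{d}_{scale}"] = float(diff[idx_tpnf])
            out[f"pn_centerdist_absdiff_mean_{d}_{scale}"] = float(diff.mean())
    return out
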