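"""Synthetic embryo cohorts and rendered zygote movies with ground truth.

The clinical source data (time-lapse videos and embryologist annotations of
implanted embryos) are private, so every downstream stage of the pipeline is
exercised on synthetic data that emulates the study conditions:

* cohorts default to the study composition of 96 miscarriage (MC) and 368
  live-birth (LB) embryos;
* morphokinetic event times are strictly ordered (tPNa < tPNf < t2 <= ... <=
  t8, hours post-ICSI) with pairwise linear correlations between consecutive
  cleavage events;
* the pronuclei are visible for 17 +/- 2.5 h (mean +/- SD) between tPNa and
  tPNf;
* class effects are planted as class-conditional normal mean shifts of a
  chosen standardized size (Cohen's d) on named columns, all other columns
  being identically distributed in both classes — the simplest structure
  under which screening recovery is provable;
* movies render a zygote as flat-intensity discs with smoothed edges
  (ooplasm, two PNs, darker NPB spots) moving along curved, linear, or
  stationary trajectories, with exact per-frame ground-truth coordinates.

Missing values are injected completely at random per cell; embryos assigned
a day-3 transfer additionally lose late cleavage annotations, mimicking the
transfer-day mix of the clinical cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import ALL_FEATURE_NAMES, EVENTS

__all__ = [
    "CohortConfig",
    "CohortData",
    "generate_cohort",
    "generate_feature_table",
    "MovieSpec",
    "GroundTruth",
    "render_zygote_movie",
    "trajectories_from_ground_truth",
]

#: Default consecutive-event linear correlations: (pair, slope, intercept,
#: residual SD in hours).  Values are chosen to produce realistic cleavage
#: timings and a t2-t3 correlation strength comparable to clinical cohorts.
DEFAULT_CORRELATIONS: tuple[tuple[tuple[str, str], float, float, float], ...] = (
    (("t2", "t3"), 1.15, 6.0, 1.3),
    (("t3", "t4"), 1.00, 2.5, 1.2),
    (("t4", "t5"), 1.00, 10.0, 2.2),
    (("t5", "t6"), 1.00, 2.5, 1.5),
    (("t6", "t7"), 1.00, 2.5, 1.5),
    (("t7", "t8"), 1.00, 3.0, 1.8),
)

CLINICS = ("H1", "H2", "H3", "H4", "H5")
DAY3_CUTOFF_H = 66.0  # events after ~66 h are unobserved for day-3 transfers


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_mc: int = 96
    n_lb: int = 368
    effect_map: Mapping[str, float] = field(default_factory=dict)
    correlation_spec: Sequence[tuple[tuple[str, str], float, float, float]] = DEFAULT_CORRELATIONS
    pn_visibility_mean: float = 17.0
    pn_visibility_sd: float = 2.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mc < 0 or self.n_lb < 0:
            raise ValueError("class counts must be non-negative")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        for name, d in self.effect_map.items():
            if not np.isfinite(d):
                raise ValueError(f"non-finite effect size for {name!r}")
        for pair, _, _, sd in self.correlation_spec:
            if not sd > 0:
                raise ValueError(f"residual SD must be positive for pair {pair}")


@dataclass
class CohortData:
    """Annotation tables and labels for one synthetic cohort."""

    events: pd.DataFrame     # embryos x 9 event times
    geometry: pd.DataFrame   # embryos x geometry annotation columns
    labels: pd.DataFrame     # label (MC/LB), clinic, transfer_day


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > lo:
            return v
    return lo + abs(rng.normal(0, sd))


def _one_profile(rng: np.random.Generator, cfg: CohortConfig) -> dict[str, float]:
    t = {}
    t["tPNa"] = _truncnorm(rng, 8.0, 1.5, 2.0)
    t["tPNf"] = t["tPNa"] + _truncnorm(rng, cfg.pn_visibility_mean, cfg.pn_visibility_sd, 6.0)
    t["t2"] = t["tPNf"] + abs(rng.normal(3.5, 1.0)) + 0.5
    for (a, b), slope, icpt, sd in cfg.correlation_spec:
        t[b] = max(slope * t[a] + icpt + rng.normal(0.0, sd), t[a] + 0.1)
    return t


def _npb_coords(rng: np.random.Generator, center: np.ndarray, radius: float,
                n: int, spacing: float = 3.2) -> np.ndarray:
    if n == 0:
        return np.empty((0, 2))
    pts: list[np.ndarray] = []
    for _ in range(5000):
        if len(pts) == n:
            break
        u = rng.uniform(-1, 1, size=2) * (radius - 2.0)
        if (u ** 2).sum() > (radius - 2.0) ** 2:
            continue
        cand = center + u
        if all(np.hypot(*(cand - p)) >= spacing for p in pts):
            pts.append(cand)
    while len(pts) < n:
        ang = rng.uniform(0, 2 * np.pi)
        pts.append(center + 0.5 * radius * np.array([np.cos(ang), np.sin(ang)]))
    return np.asarray(pts)


def _one_geometry(rng: np.random.Generator) -> dict:
    r_o = rng.normal(60.0, 4.0)
    z_in = r_o + abs(rng.normal(6.0, 1.0))
    z_out = z_in + abs(rng.normal(12.0, 2.0))
    r_s = float(np.clip(rng.normal(11.0, 1.0), 8.0, 14.0))
    r_l = r_s + float(np.clip(abs(rng.normal(2.0, 0.7)), 0.2, 5.0))
    center = np.array([75.0, 75.0])
    for _ in range(200):
        ang = rng.uniform(0, 2 * np.pi)
        mid = center + rng.normal(12.0, 4.0) * np.array([np.cos(ang), np.sin(ang)])
        axis = rng.uniform(0, 2 * np.pi)
        u = np.array([np.cos(axis), np.sin(axis)])
        half = 0.5 * (r_s + r_l + 2.0)
        c_l, c_s = mid + half * u, mid - half * u
        if (np.linalg.norm(c_l - center) + r_l < r_o
                and np.linalg.norm(c_s - center) + r_s < r_o):
            break
    n_s, n_l = int(rng.integers(2, 8)), int(rng.integers(2, 8))
    return {
        "ooplasm_cx": center[0], "ooplasm_cy": center[1], "ooplasm_radius": r_o,
        "zona_inner_radius": z_in, "zona_outer_radius": z_out,
        "pn_small_cx": c_s[0], "pn_small_cy": c_s[1], "pn_small_radius": r_s,
        "pn_large_cx": c_l[0], "pn_large_cy": c_l[1], "pn_large_radius": r_l,
        "npb_small": json.dumps(np.round(_npb_coords(rng, c_s, r_s, n_s), 3).tolist()),
        "npb_large": json.dumps(np.round(_npb_coords(rng, c_l, r_l, n_l), 3).tolist()),
        "fragmentation_2c": float(rng.choice([0, 5, 10, 15, 20, 25],
                                             p=[0.35, 0.25, 0.2, 0.1, 0.06, 0.04])),
        "fragmentation_4c": float(rng.choice([0, 5, 10, 15, 20, 25],
                                             p=[0.3, 0.25, 0.2, 0.12, 0.08, 0.05])),
        "symmetry_2c": float(rng.choice([1, 2, 3, 4], p=[0.5, 0.3, 0.15, 0.05])),
        "symmetry_4c": float(rng.choice([1, 2, 3, 4], p=[0.45, 0.3, 0.17, 0.08])),
        "cleavage_plane_angle": float(rng.uniform(0.0, 180.0)),
    }


#: geometry columns eligible for planted effects and missingness
_GEOM_EFFECT_COLS = ("ooplasm_radius", "zona_inner_radius", "zona_outer_radius",
                     "pn_small_radius", "pn_large_radius",
                     "fragmentation_2c", "fragmentation_4c",
                     "symmetry_2c", "symmetry_4c", "cleavage_plane_angle")


def generate_cohort(config: CohortConfig) -> CohortData:
    """Generate labeled morphokinetic and geometry annotations.

    Returns exactly ``n_mc + n_lb`` embryos with label counts (n_mc, n_lb).
    Columns named in ``config.effect_map`` (event or geometry annotation
    columns) are shifted in the MC class by d standard deviations.
    Reproducible: a fixed seed gives byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_mc + config.n_lb
    ids = [f"e{i:04d}" for i in range(n)]
    labels = np.array(["MC"] * config.n_mc + ["LB"] * config.n_lb)
    perm = rng.permutation(n)
    labels = labels[perm]

    events = pd.DataFrame([_one_profile(rng, config) for _ in range(n)],
                          index=ids, columns=list(EVENTS))
    geometry = pd.DataFrame([_one_geometry(rng) for _ in range(n)], index=ids)
    meta = pd.DataFrame({
        "label": labels,
        "clinic": rng.choice(CLINICS, size=n, p=[0.1, 0.3, 0.25, 0.2, 0.15]),
        "transfer_day": rng.choice([3, 5], size=n, p=[0.55, 0.45]),
    }, index=ids)

    is_mc = labels == "MC"
    for name, d in config.effect_map.items():
        if name in events.columns:
            tgt = events
        elif name in _GEOM_EFFECT_COLS:
            tgt = geometry
        else:
            raise KeyError(f"effect_map names unknown annotation column {name!r}")
        sd = float(tgt[name].std(ddof=1)) if n > 1 else 1.0
        tgt.loc[is_mc, name] += d * sd

    # re-enforce chronology after planted shifts
    ev = events.to_numpy()
    for j in range(1, ev.shape[1]):
        ev[:, j] = np.maximum(ev[:, j], ev[:, j - 1] + 0.1)
    events.loc[:, :] = ev

    if config.missing_rate > 0:
        mask = rng.random(events.shape) < config.missing_rate
        events[mask] = np.nan
        gcols = list(_GEOM_EFFECT_COLS)
        gmask = rng.random((n, len(gcols))) < config.missing_rate
        gvals = geometry[gcols].to_numpy(float)
        gvals[gmask] = np.nan
        geometry[gcols] = gvals
    # day-3 transfers: late events unobserved
    day3 = (meta["transfer_day"] == 3).to_numpy()
    late = events.to_numpy()
    late[day3] = np.where(late[day3] > DAY3_CUTOFF_H, np.nan, late[day3])
    events.loc[:, :] = late
    return CohortData(events=events, geometry=geometry, labels=meta)


def generate_feature_table(config: CohortConfig) -> pd.DataFrame:
    """Generate a feature-space cohort: the 314 catalog columns + metadata.

    Features are unit-variance normal noise; columns named in ``effect_map``
    get a class-conditional mean shift of d in the MC class (Cohen's d, since
    both class SDs are 1).  Cells go missing completely at random at
    ``missing_rate``.  The returned frame carries ``label``, ``clinic`` and
    ``transfer_day`` metadata columns alongside the features.
    """
    for name in config.effect_map:
        if name not in ALL_FEATURE_NAMES:
            raise KeyError(f"effect_map names unknown feature {name!r}")
    rng = np.random.default_rng(config.seed)
    n = config.n_mc + config.n_lb
    labels = np.array(["MC"] * config.n_mc + ["LB"] * config.n_lb)[rng.permutation(n)]
    X = rng.normal(size=(n, len(ALL_FEATURE_NAMES)))
    df = pd.DataFrame(X, columns=list(ALL_FEATURE_NAMES),
                      index=[f"e{i:04d}" for i in range(n)])
    is_mc = labels == "MC"
    for name, d in config.effect_map.items():
        df.loc[is_mc, name] += d
    if config.missing_rate > 0:
        mask = rng.random(df.shape) < config.missing_rate
        df[mask] = np.nan
    df["label"] = labels
    df["clinic"] = rng.choice(CLINICS, size=n, p=[0.1, 0.3, 0.25, 0.2, 0.15])
    df["transfer_day"] = rng.choice([3, 5], size=n, p=[0.55, 0.45])
    return df


# ------------------------------------------------------------------ movies

@dataclass
class MovieSpec:
    """Rendering parameters for one synthetic zygote movie."""

    frame_size: int = 150
    n_frames: int = 34
    frame_interval_min: float = 30.0
    ooplasm_radius: float = 55.0
    pn_radii: tuple[float, float] = (10.0, 13.0)   # (small, large), pixels
    npb_count: int = 4
    trajectory_kind: Literal["curved", "linear", "stationary"] = "linear"
    speed: float = 0.8                              # pixels/frame
    noise_sd: float = 3.0                           # gray levels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if max(self.pn_radii) >= self.ooplasm_radius:
            raise ValueError("PN radii must be smaller than the ooplasm radius")
        if self.trajectory_kind not in ("curved", "linear", "stationary"):
            raise ValueError(f"unknown trajectory kind {self.trajectory_kind!r}")


@dataclass
class GroundTruth:
    """Exact per-frame coordinates used to render a movie."""

    ooplasm_center: np.ndarray            # (2,)
    ooplasm_radius: float
    pn_small: np.ndarray                  # (T, 2)
    pn_large: np.ndarray                  # (T, 2)
    npb_small: np.ndarray                 # (T, k, 2)
    npb_large: np.ndarray                 # (T, k, 2)
    pn_radii: tuple[float, float] = (10.0, 13.0)
    frame_interval_min: float = 30.0

    def to_json(self, path) -> None:
        payload = {
            "ooplasm_center": np.asarray(self.ooplasm_center).tolist(),
            "ooplasm_radius": float(self.ooplasm_radius),
            "pn_small": np.asarray(self.pn_small).tolist(),
            "pn_large": np.asarray(self.pn_large).tolist(),
            "npb_small": np.asarray(self.npb_small).tolist(),
            "npb_large": np.asarray(self.npb_large).tolist(),
            "pn_radii": list(self.pn_radii),
            "frame_interval_min": self.frame_interval_min,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(ooplasm_center=np.asarray(d["ooplasm_center"]),
                   ooplasm_radius=d["ooplasm_radius"],
                   pn_small=np.asarray(d["pn_small"]),
                   pn_large=np.asarray(d["pn_large"]),
                   npb_small=np.asarray(d["npb_small"]),
                   npb_large=np.asarray(d["npb_large"]),
                   pn_radii=tuple(d["pn_radii"]),
                   frame_interval_min=d["frame_interval_min"])


_BG, _OOPLASM, _PN, _NPB = 30.0, 120.0, 175.0, 60.0
_EDGE = 2.0         # edge-smoothing width, pixels
_NPB_RADIUS = 1.6


def _soft_disc(dist: np.ndarray, radius: float) -> np.ndarray:
    return np.clip((radius - dist) / _EDGE + 0.5, 0.0, 1.0)


def render_zygote_movie(spec: MovieSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a grayscale uint8 stack and its exact ground truth.

    The two PN discs (each containing ``npb_count`` darker NPB spots) move
    rigidly per ``trajectory_kind``: pure translation at ``speed``
    pixels/frame (linear), rigid rotation about the ooplasm center with arc
    speed ``speed`` (curved), or no motion (stationary).  Additive Gaussian
    noise with SD ``noise_sd`` is applied before quantization.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.frame_size
    center = np.array([(size - 1) / 2.0, (size - 1) / 2.0])
    r_s, r_l = spec.pn_radii
    t_axis = np.arange(spec.n_frames)

    # initial placement: PN pair straddling a midpoint offset from center
    ang = rng.uniform(0, 2 * np.pi)
    mid = center + 0.35 * spec.ooplasm_radius * np.array([np.cos(ang), np.sin(ang)])
    axis = rng.uniform(0, 2 * np.pi)
    u = np.array([np.cos(axis), np.sin(axis)])
    half = 0.5 * (r_s + r_l + 2.0)
    c_l0, c_s0 = mid + half * u, mid - half * u
    for c0, r0 in ((c_s0, r_s), (c_l0, r_l)):
        if np.linalg.norm(c0 - center) + r0 >= spec.ooplasm_radius:
            raise ValueError("PN initially outside the ooplasm")

    npb_s0 = _npb_coords(rng, c_s0, r_s, spec.npb_count)
    npb_l0 = _npb_coords(rng, c_l0, r_l, spec.npb_count)

    def transform(points: np.ndarray, t: int) -> np.ndarray:
        if spec.trajectory_kind == "stationary" or spec.speed == 0:
            return points.copy()
        if spec.trajectory_kind == "linear":
            direction = center - mid
            nrm = np.linalg.norm(direction)
            d_hat = direction / nrm if nrm > 0 else np.array([1.0, 0.0])
            return points + spec.speed * t * d_hat
        orbit = max(np.linalg.norm(c_s0 - center), np.linalg.norm(c_l0 - center))
        omega = spec.speed / max(orbit, 1e-9)
        th = omega * t
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return (points - center) @ rot.T + center

    pn_s = np.asarray([transform(c_s0[None, :], t)[0] for t in t_axis])
    pn_l = np.asarray([transform(c_l0[None, :], t)[0] for t in t_axis])
    npb_s = np.asarray([transform(npb_s0, t) for t in t_axis])
    npb_l = np.asarray([transform(npb_l0, t) for t in t_axis])

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    d_oo = np.hypot(xx - center[0], yy - center[1])
    base = _BG + (_OOPLASM - _BG) * _soft_disc(d_oo, spec.ooplasm_radius)

    stack = np.empty((spec.n_frames, size, size), dtype=np.uint8)
    for t in t_axis:
        img = base.copy()
        for c, r in ((pn_s[t], r_s), (pn_l[t], r_l)):
            m = _soft_disc(np.hypot(xx - c[0], yy - c[1]), r)
            img = img * (1 - m) + _PN * m
        for spots in (npb_s[t], npb_l[t]):
            for c in spots:
                m = _soft_disc(np.hypot(xx - c[0], yy - c[1]), _NPB_RADIUS)
                img = img * (1 - m) + _NPB * m
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        stack[t] = np.clip(img, 0, 255).astype(np.uint8)

    gt = GroundTruth(ooplasm_center=center, ooplasm_radius=spec.ooplasm_radius,
                     pn_small=pn_s, pn_large=pn_l, npb_small=npb_s, npb_large=npb_l,
                     pn_radii=spec.pn_radii, frame_interval_min=spec.frame_interval_min)
    return stack, gt


def trajectories_from_ground_truth(gt: GroundTruth, t_start_h: float = 0.0):
    """Build exact PN trajectories from ground truth (no tracking involved).

    Useful as an annotation-level input to :func:`pn_dynamics_features` and
    as the oracle against which tracked trajectories are validated.
    """
    from .tracking import PNTrajectory

    dt_h = gt.frame_interval_min / 60.0
    n = len(gt.pn_small)
    t_fwd = t_start_h + dt_h * np.arange(n)
    trajs = {}
    for pn, pos in (("small", np.asarray(gt.pn_small)), ("large", np.asarray(gt.pn_large))):
        rel = pos - np.asarray(gt.ooplasm_center)
        trajs[(pn, "fwd")] = PNTrajectory(pn=pn, direction="fwd", positions=rel,
                                          times=t_fwd, n_tracks=15, reliable=True)
        trajs[(pn, "rev")] = PNTrajectory(pn=pn, direction="rev", positions=rel[::-1],
                                          times=t_fwd[::-1], n_tracks=15, reliable=True)
    return trajs
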