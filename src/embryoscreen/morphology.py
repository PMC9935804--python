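"""Static morphological features measured at the reference frame.

All geometry is annotated at the third frame before pronuclear fading
(roughly one hour before tPNf), on the central focal plane.  Coordinates use
image conventions: origin top-left, x rightward, y downward, pixel units.

Of the 35 features, the first-cleavage-plane orientation angle is consumed
as an annotated scalar (it is measured from a z-stack, outside this
package's scope); everything else is computed here from the annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import MORPHOLOGY_NAMES

__all__ = ["GeometryAnnotation", "npb_features", "morphology_catalog"]


def _pts(coords) -> np.ndarray:
    a = np.asarray(coords, dtype=float) if coords is not None else np.empty((0, 2))
    return a.reshape(-1, 2)


@dataclass
class GeometryAnnotation:
    """Geometry of one zygote at the reference frame.

    Any field may be ``None`` (unannotated); missingness propagates into the
    feature vector as NaN rather than raising.
    """

    ooplasm_center: Optional[tuple[float, float]] = None
    ooplasm_radius: Optional[float] = None
    zona_inner_radius: Optional[float] = None
    zona_outer_radius: Optional[float] = None
    pn_small_center: Optional[tuple[float, float]] = None
    pn_small_radius: Optional[float] = None
    pn_large_center: Optional[tuple[float, float]] = None
    pn_large_radius: Optional[float] = None
    npb_small: Sequence[tuple[float, float]] = field(default_factory=list)
    npb_large: Sequence[tuple[float, float]] = field(default_factory=list)
    fragmentation_2c: Optional[float] = None
    fragmentation_4c: Optional[float] = None
    symmetry_2c: Optional[float] = None
    symmetry_4c: Optional[float] = None
    cleavage_plane_angle: Optional[float] = None

    def __post_init__(self) -> None:
        for r in (self.ooplasm_radius, self.zona_inner_radius, self.zona_outer_radius,
                  self.pn_small_radius, self.pn_large_radius):
            if r is not None and not (r > 0):
                raise ValueError(f"radii must be positive, got {r}")


def _pairwise_max(points: np.ndarray) -> float:
    """Maximum pairwise distance; 0 for a single point, NaN for none."""
    if len(points) == 0:
        return np.nan
    if len(points) == 1:
        return 0.0
    d = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((d ** 2).sum(-1)).max())


def _pairwise_mean(points: np.ndarray) -> float:
    if len(points) == 0:
        return np.nan
    if len(points) == 1:
        return 0.0
    dists = [float(np.hypot(*(p - q))) for p, q in combinations(points, 2)]
    return float(np.mean(dists))


def _spread(points: np.ndarray) -> float:
    """RMS distance of points from their centroid."""
    if len(points) == 0:
        return np.nan
    c = points.mean(axis=0)
    return float(np.sqrt(((points - c) ** 2).sum(axis=1).mean()))


def npb_features(geom: GeometryAnnotation) -> dict[str, float]:
    """NPB count (4) and spatial-distribution (11) features, including f1.

    f1 is the maximum pairwise distance between NPBs within the *small* PN,
    normalized by the small-PN radius.  A single NPB gives 0 (the maximum
    over an empty pair set of one point is defined as zero); zero NPBs give
    NaN — "unmeasured" is distinct from "measurably compact".
    """
    small, large = _pts(geom.npb_small), _pts(geom.npb_large)
    n_s = len(small) if geom.npb_small is not None else np.nan
    n_l = len(large) if geom.npb_large is not None else np.nan
    out: dict[str, float] = {
        "npb_count_small": float(n_s),
        "npb_count_large": float(n_l),
        "npb_count_total": float(n_s + n_l),
        "npb_count_diff": float(n_l - n_s),
    }
    max_s, max_l = _pairwise_max(small), _pairwise_max(large)
    r_s = geom.pn_small_radius or np.nan
    r_l = geom.pn_large_radius or np.nan
    out["npb_maxdist_norm_small"] = max_s / r_s
    out["npb_maxdist_small"] = max_s
    out["npb_maxdist_large"] = max_l
    out["npb_maxdist_norm_large"] = max_l / r_l
    out["npb_meandist_small"] = _pairwise_mean(small)
    out["npb_meandist_large"] = _pairwise_mean(large)
    out["npb_spread_small"] = _spread(small)
    out["npb_spread_large"] = _spread(large)
    if len(small) and len(large):
        cross = np.sqrt(((small[:, None, :] - large[None, :, :]) ** 2).sum(-1)).ravel()
        out["npb_cross_mindist"] = float(cross.min())
        out["npb_cross_meandist"] = float(cross.mean())
        out["npb_cross_maxdist"] = float(cross.max())
    else:
        out["npb_cross_mindist"] = out["npb_cross_meandist"] = out["npb_cross_maxdist"] = np.nan
    return out


def _dist(a, b) -> float:
    if a is None or b is None:
        return np.nan
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def morphology_catalog(geom: GeometryAnnotation) -> pd.Series:
    """The 35 morphology features, in frozen catalog order.

    Missing annotations propagate as NaN; missingness is data, not error.
    """
    nan = np.nan
    r_s = geom.pn_small_radius if geom.pn_small_radius is not None else nan
    r_l = geom.pn_large_radius if geom.pn_large_radius is not None else nan
    r_o = geom.ooplasm_radius if geom.ooplasm_radius is not None else nan
    z_i = geom.zona_inner_radius if geom.zona_inner_radius is not None else nan
    z_o = geom.zona_outer_radius if geom.zona_outer_radius is not None else nan
    out: dict[str, float] = {
        "symmetry_2c": geom.symmetry_2c if geom.symmetry_2c is not None else nan,
        "symmetry_4c": geom.symmetry_4c if geom.symmetry_4c is not None else nan,
        "fragmentation_2c": geom.fragmentation_2c if geom.fragmentation_2c is not None else nan,
        "fragmentation_4c": geom.fragmentation_4c if geom.fragmentation_4c is not None else nan,
        "pn_radius_small": r_s,
        "pn_radius_large": r_l,
        "pn_area_small": np.pi * r_s ** 2,
        "pn_area_large": np.pi * r_l ** 2,
        "pn_radius_ratio": r_l / r_s,
        "pn_area_ratio": (r_l / r_s) ** 2,
        "pn_radius_diff": r_l - r_s,
        "pn_offset_small": _dist(geom.pn_small_center, geom.ooplasm_center),
        "pn_offset_large": _dist(geom.pn_large_center, geom.ooplasm_center),
        "pn_separation": _dist(geom.pn_small_center, geom.pn_large_center),
    }
    out.update(npb_features(geom))
    out["cleavage_plane_angle"] = (
        geom.cleavage_plane_angle if geom.cleavage_plane_angle is not None else nan
    )
    out["ooplasm_radius"] = r_o  # f2: identity passthrough of the annotation
    out["zona_inner_radius"] = z_i
    out["zona_outer_radius"] = z_o
    out["zona_thickness"] = z_o - z_i
    out["perivitelline_gap"] = z_i - r_o
    return pd.Series(out, dtype=float).reindex(list(MORPHOLOGY_NAMES))
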