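"""Assembly of the 314-column FeatureTable from annotations and movies.

One row per embryo: 35 morphology + 117 morphokinetic + 162 PN-dynamics
features, in frozen catalog order, plus label/clinic/transfer-day metadata.
Missing annotations propagate as NaN.  DLR regression lines are fitted on
the live-birth embryos of the supplied cohort (the "global" fit); for
leakage-free cross-validation a refit hook restricted to each training
split is provided instead.
"""

from __future__ import annotations

import json
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .catalog import ALL_FEATURE_NAMES
from .morphokinetics import MorphokineticProfile, fit_dlr_lines, morphokinetic_features
from .morphology import GeometryAnnotation, morphology_catalog
from .simulate import CohortData, GroundTruth
from .tracking import PNTrajectory, pn_dynamics_features, track_pn

__all__ = ["geometry_row_to_annotation", "build_feature_table",
           "pn_features_from_movie", "make_dlr_refit"]


def _opt(row: Mapping, key: str):
    v = row.get(key) if hasattr(row, "get") else row[key]
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return v


def geometry_row_to_annotation(row: Mapping) -> GeometryAnnotation:
    """Deserialize one geometry-table row (NPB coordinates are JSON lists)."""
    def center(prefix: str):
        cx, cy = _opt(row, f"{prefix}_cx"), _opt(row, f"{prefix}_cy")
        return None if cx is None or cy is None else (float(cx), float(cy))

    def npbs(key: str):
        v = _opt(row, key)
        if v is None:
            return []
        return json.loads(v) if isinstance(v, str) else v

    return GeometryAnnotation(
        ooplasm_center=center("ooplasm"),
        ooplasm_radius=_opt(row, "ooplasm_radius"),
        zona_inner_radius=_opt(row, "zona_inner_radius"),
        zona_outer_radius=_opt(row, "zona_outer_radius"),
        pn_small_center=center("pn_small"),
        pn_small_radius=_opt(row, "pn_small_radius"),
        pn_large_center=center("pn_large"),
        pn_large_radius=_opt(row, "pn_large_radius"),
        npb_small=npbs("npb_small"),
        npb_large=npbs("npb_large"),
        fragmentation_2c=_opt(row, "fragmentation_2c"),
        fragmentation_4c=_opt(row, "fragmentation_4c"),
        symmetry_2c=_opt(row, "symmetry_2c"),
        symmetry_4c=_opt(row, "symmetry_4c"),
        cleavage_plane_angle=_opt(row, "cleavage_plane_angle"),
    )


def pn_features_from_movie(stack: np.ndarray, gt: GroundTruth, *,
                           use_ground_truth_centers: bool = True,
                           t_start_h: float = 0.0, seed: int = 0) -> dict[str, float]:
    """Track both PNs (forward and reverse) in a stack and derive 162 features.

    Seed discs come from the ground-truth geometry at the episode's starting
    frame; the embryo frame of reference uses the ground-truth ooplasm
    center when available, otherwise the per-frame intensity centroid.
    """
    r_s, r_l = gt.pn_radii
    n = len(stack)
    centers = (np.tile(np.asarray(gt.ooplasm_center, float), (n, 1))
               if use_ground_truth_centers else None)
    trajs: dict[tuple[str, str], PNTrajectory] = {}
    for pn, radius, path in (("small", r_s, np.asarray(gt.pn_small)),
                             ("large", r_l, np.asarray(gt.pn_large))):
        for direction in ("fwd", "rev"):
            start = path[0] if direction == "fwd" else path[-1]
            trajs[(pn, direction)] = track_pn(
                stack, tuple(start), radius, direction,
                frame_interval_min=gt.frame_interval_min, t_start_h=t_start_h,
                ooplasm_centers=centers, pn=pn, seed=seed)
    return pn_dynamics_features(trajs, gt.ooplasm_radius)


def build_feature_table(cohort: CohortData, *,
                        dlr_fit: str = "global",
                        pn_features: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Build the embryos x 314 FeatureTable from a cohort's annotations.

    ``dlr_fit="global"`` fits the 36 DLR lines on all LB embryos of the
    cohort (the single-pass behavior); ``"none"`` leaves DLR columns NaN,
    for workflows that refit lines per CV fold via :func:`make_dlr_refit`.
    ``pn_features`` (embryos x 162, e.g. from movies) is merged when given;
    otherwise the PN-dynamics block is NaN.
    """
    if dlr_fit not in ("global", "none"):
        raise ValueError("dlr_fit must be 'global' or 'none'")
    lines = {}
    if dlr_fit == "global":
        lb_ids = cohort.labels.index[cohort.labels["label"] == "LB"]
        lines = fit_dlr_lines(cohort.events.loc[lb_ids])
    rows = {}
    for eid in cohort.events.index:
        morph = morphology_catalog(geometry_row_to_annotation(cohort.geometry.loc[eid]))
        profile = MorphokineticProfile.from_mapping(cohort.events.loc[eid].to_dict())
        mk = morphokinetic_features(profile, lines)
        rows[eid] = {**morph.to_dict(), **mk}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.reindex(columns=list(ALL_FEATURE_NAMES))
    if pn_features is not None:
        table.loc[pn_features.index, pn_features.columns] = pn_features
    return table.join(cohort.labels)


def make_dlr_refit(events: pd.DataFrame, labels: pd.Series):
    """Fold-wise DLR hook for leakage-free cross-validation.

    Returns ``hook(table, train_idx)`` that refits the 36 regression lines on
    the *LB members of the training split only* and recomputes every embryo's
    DLR columns against those lines.  Permuting or relabeling rows outside
    the training split cannot change any line.
    """
    from .morphokinetics import dlr as _dlr

    def hook(table: pd.DataFrame, train_idx: np.ndarray) -> pd.DataFrame:
        train_ids = table.index[np.asarray(train_idx)]
        lb_ids = [i for i in train_ids if labels.loc[i] == "LB"]
        lines = fit_dlr_lines(events.loc[lb_ids])
        out = {}
        for eid in table.index:
            profile = MorphokineticProfile.from_mapping(events.loc[eid].to_dict())
            out[eid] = {f"dlr_{a}_{b}": _dlr(profile, line)
                        for (a, b), line in lines.items()}
        return pd.DataFrame.from_dict(out, orient="index")

    return hook
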