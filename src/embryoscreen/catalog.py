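"""Frozen catalog of the 314 embryo features.

The feature set spans three groups measured on one preimplantation embryo:

* **morphology** (35) — static geometry at the reference frame (the third
  frame before pronuclear fading, tPNf): blastomere symmetry and
  fragmentation grades, pronucleus (PN) size and location, nucleolus
  precursor body (NPB) counts and spatial arrangement, first-cleavage-plane
  orientation, and ooplasm / zona pellucida radii.
* **morphokinetics** (117) — the nine annotated event times (tPNa, tPNf,
  t2…t8, hours post-ICSI), all 36 pairwise intervals, all 36 pairwise time
  ratios, and 36 distance-from-linear-regression (DLR) values.
* **pn_dynamics** (162) — optical-flow trajectory summaries of the two
  pronuclei tracked forward (tPNa→tPNf) and reverse: step-size and velocity
  statistics (72), inter-PN distance statistics (18), and PN-to-embryo-center
  distance statistics (72).

Only the group cardinalities and a handful of named features (f1…f6) are
pinned externally; the per-feature definitions inside each group are fixed
here, once, so that the 314 total is stable and testable.  The rendered data
dictionary shipped in ``docs/data_dictionary.md`` is generated from this
module.
"""

from __future__ import annotations

import pandas as pd

#: Morphokinetic events in chronological catalog order.
EVENTS: tuple[str, ...] = ("tPNa", "tPNf", "t2", "t3", "t4", "t5", "t6", "t7", "t8")

#: All C(9,2)=36 unordered event pairs in chronological (earlier, later) order.
EVENT_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (EVENTS[i], EVENTS[j]) for i in range(len(EVENTS)) for j in range(i + 1, len(EVENTS))
)

# ---------------------------------------------------------------- morphology

MORPHOLOGY_NAMES: tuple[str, ...] = (
    # blastomere size symmetry grades (2)
    "symmetry_2c",
    "symmetry_4c",
    # fragmentation percentage (2)
    "fragmentation_2c",
    "fragmentation_4c",
    # PN size (7)
    "pn_radius_small",
    "pn_radius_large",
    "pn_area_small",
    "pn_area_large",
    "pn_radius_ratio",
    "pn_area_ratio",
    "pn_radius_diff",
    # PN location (3)
    "pn_offset_small",
    "pn_offset_large",
    "pn_separation",
    # NPB number distributions (4)
    "npb_count_small",
    "npb_count_large",
    "npb_count_total",
    "npb_count_diff",
    # NPB spatial distributions within and between PNs (11)
    "npb_maxdist_norm_small",   # f1
    "npb_maxdist_small",
    "npb_maxdist_large",
    "npb_maxdist_norm_large",
    "npb_meandist_small",
    "npb_meandist_large",
    "npb_spread_small",
    "npb_spread_large",
    "npb_cross_mindist",
    "npb_cross_meandist",
    "npb_cross_maxdist",
    # first cleavage plane orientation (1) — consumed as an annotation
    "cleavage_plane_angle",
    # ooplasm and zona pellucida radii (5)
    "ooplasm_radius",           # f2
    "zona_inner_radius",
    "zona_outer_radius",
    "zona_thickness",
    "perivitelline_gap",
)

# ------------------------------------------------------------ morphokinetics


def _mk_names() -> tuple[str, ...]:
    names = list(EVENTS)
    names += [f"ivl_{a}_{b}" for a, b in EVENT_PAIRS]
    names += [f"ratio_{a}_{b}" for a, b in EVENT_PAIRS]
    names += [f"dlr_{a}_{b}" for a, b in EVENT_PAIRS]
    return tuple(names)


MORPHOKINETIC_NAMES: tuple[str, ...] = _mk_names()

# -------------------------------------------------------------- pn dynamics

#: Per-series summary statistics for step/velocity series ("total" = path sum).
PATH_STATS: tuple[str, ...] = ("min", "max", "mean", "median", "std", "first", "last", "total")
#: Per-series summary statistics for distance series.
DIST_STATS: tuple[str, ...] = ("min", "max", "mean", "median", "std", "first", "last", "range")
#: Inter-PN separation statistics (one extra spread measure to reach 9).
SEP_STATS: tuple[str, ...] = DIST_STATS + ("iqr",)

PN_SIDES: tuple[str, ...] = ("small", "large")
DIRECTIONS: tuple[str, ...] = ("fwd", "rev")


def _pn_dyn_names() -> tuple[str, ...]:
    names: list[str] = []
    # step size & velocity: 8 stats x 2 quantities x 2 PNs x 2 directions = 64
    # + cross-PN comparison features 2 x 2 quantities x 2 directions = 8 -> 72
    for qty in ("step", "velocity"):
        for pn in PN_SIDES:
            for d in DIRECTIONS:
                names += [f"pn_{qty}_{s}_{pn}_{d}" for s in PATH_STATS]
    for qty in ("step", "velocity"):
        for d in DIRECTIONS:
            names.append(f"pn_{qty}_max_ratio_{d}")     # f5 for (step, fwd)
            names.append(f"pn_{qty}_min_absdiff_{d}")   # cf1/cf3-style
    # inter-PN distances: 9 stats x 2 directions = 18
    for d in DIRECTIONS:
        names += [f"pn_sep_{s}_{d}" for s in SEP_STATS]
    # PN distance from embryo center: 8 stats x 2 PNs x 2 dirs x {raw,norm} = 64
    # + |large - small| at tPNf and on average, x 2 dirs x {raw,norm} = 8 -> 72
    for scale in ("raw", "norm"):
        for pn in PN_SIDES:
            for d in DIRECTIONS:
                names += [f"pn_centerdist_{s}_{pn}_{d}_{scale}" for s in DIST_STATS]
    for scale in ("raw", "norm"):
        for d in DIRECTIONS:
            names.append(f"pn_centerdist_absdiff_tpnf_{d}_{scale}")  # f6 for (fwd, raw)
            names.append(f"pn_centerdist_absdiff_mean_{d}_{scale}")
    return tuple(names)


PN_DYNAMICS_NAMES: tuple[str, ...] = _pn_dyn_names()

ALL_FEATURE_NAMES: tuple[str, ...] = MORPHOLOGY_NAMES + MORPHOKINETIC_NAMES + PN_DYNAMICS_NAMES

#: Index of each feature in the frozen catalog order (used for tie-breaking).
CATALOG_INDEX: dict[str, int] = {n: i for i, n in enumerate(ALL_FEATURE_NAMES)}

#: The six selected features of the final non-redundant subset.
SELECTED_FEATURES: dict[str, str] = {
    "f1": "npb_maxdist_norm_small",
    "f2": "ooplasm_radius",
    "f3": "dlr_t2_t3",
    "f4": "dlr_t5_t6",
    "f5": "pn_step_max_ratio_fwd",
    "f6": "pn_centerdist_absdiff_tpnf_fwd_raw",
}

GROUPS: dict[str, tuple[str, ...]] = {
    "morphology": MORPHOLOGY_NAMES,
    "morphokinetics": MORPHOKINETIC_NAMES,
    "pn_dynamics": PN_DYNAMICS_NAMES,
}

_DESCRIPTIONS = {
    "symmetry": "blastomere size symmetry grade (1 = even .. 4 = very uneven)",
    "fragmentation": "fragmentation percentage of embryo volume",
    "pn_radius": "pronucleus radius, pixels",
    "pn_area": "pronucleus disc area, square pixels",
    "pn_offset": "PN-center distance from the ooplasm center, pixels",
    "pn_separation": "distance between the two PN centers, pixels",
    "npb_count": "number of nucleolus precursor bodies",
    "npb_maxdist": "maximum pairwise NPB distance within one PN, pixels",
    "npb_maxdist_norm": "maximum pairwise NPB distance / PN radius (f1 for the small PN)",
    "npb_meandist": "mean pairwise NPB distance within one PN, pixels",
    "npb_spread": "RMS NPB distance from the NPB centroid, pixels",
    "npb_cross": "NPB-to-NPB distance between the two PNs, pixels",
    "cleavage_plane_angle": "first-cleavage-plane orientation angle, degrees (annotated)",
    "ooplasm_radius": "ooplasm radius, pixels (f2)",
    "zona": "zona pellucida radius / thickness, pixels",
    "perivitelline_gap": "zona inner radius minus ooplasm radius, pixels",
    "event": "morphokinetic event time, hours post-ICSI",
    "ivl": "event-time interval t_later - t_earlier, hours",
    "ratio": "event-time ratio t_later / t_earlier",
    "dlr": "unsigned distance from the live-birth regression line in the event-pair plane, hours",
    "pn_step": "per-frame PN displacement statistics, pixels",
    "pn_velocity": "per-frame PN speed statistics, pixels/hour",
    "pn_sep": "inter-PN distance statistics, pixels",
    "pn_centerdist": "PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius",
}


def _describe(name: str) -> str:
    for key in sorted(_DESCRIPTIONS, key=len, reverse=True):
        if name.startswith(key):
            return _DESCRIPTIONS[key]
    if name in EVENTS:
        return _DESCRIPTIONS["event"]
    return ""


def data_dictionary() -> pd.DataFrame:
    """Return the full 314-row data dictionary (name, group, description)."""
    rows = []
    for group, names in GROUPS.items():
        for n in names:
            alias = next((k for k, v in SELECTED_FEATURES.items() if v == n), "")
            rows.append({"feature": n, "group": group, "alias": alias, "description": _describe(n)})
    return pd.DataFrame(rows)
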