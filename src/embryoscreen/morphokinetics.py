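"""Morphokinetic event-time features and the DLR statistic.

Morphokinetic profiles are the annotated times (hours post-ICSI) of
pronuclear appearance (tPNa) and fading (tPNf) and of the 2- to 8-blastomere
cleavages (t2…t8).  From the nine events this module derives all 36 pairwise
intervals and 36 pairwise time ratios, plus 36 DLR values.

DLR (distance from linear regression): event-time pairs of live-birth (LB)
embryos are strongly linearly correlated; for each of the 36 event pairs an
ordinary-least-squares line is fitted on LB embryos only, and DLR is an
embryo's shortest (perpendicular) Euclidean distance from that line in the
(t_earlier, t_later) plane.  It quantifies how far an embryo sits from the
average profile of well-developing positively implanted embryos.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import EVENT_PAIRS, EVENTS

__all__ = [
    "MorphokineticProfile",
    "RegressionLine",
    "pairwise_intervals_and_ratios",
    "fit_dlr_lines",
    "lines_to_json",
    "lines_from_json",
    "dlr",
    "dlr_features",
    "morphokinetic_features",
]


@dataclass
class MorphokineticProfile:
    """Event times for one embryo; missing events are ``None``/NaN."""

    tPNa: Optional[float] = None
    tPNf: Optional[float] = None
    t2: Optional[float] = None
    t3: Optional[float] = None
    t4: Optional[float] = None
    t5: Optional[float] = None
    t6: Optional[float] = None
    t7: Optional[float] = None
    t8: Optional[float] = None

    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "MorphokineticProfile":
        return cls(**{e: m.get(e) for e in EVENTS})

    def get(self, event: str) -> float:
        v = getattr(self, event)
        return np.nan if v is None else float(v)

    def as_series(self) -> pd.Series:
        return pd.Series({e: self.get(e) for e in EVENTS}, dtype=float)

    def validate(self) -> None:
        """Check positivity and chronological order of present values."""
        vals = self.as_series()
        present = vals.dropna()
        if (present <= 0).any():
            raise ValueError("event times must be strictly positive")
        if not present.is_monotonic_increasing:
            raise ValueError("event times out of chronological order")


def pairwise_intervals_and_ratios(p: MorphokineticProfile) -> dict[str, float]:
    """All 36 pairwise intervals and 36 pairwise ratios (72 values).

    Each unordered event pair is taken in chronological catalog order
    (earlier, later): interval = t_later - t_earlier, ratio = t_later /
    t_earlier.  Any missing operand, or a zero denominator, yields NaN.
    """
    out: dict[str, float] = {}
    for a, b in EVENT_PAIRS:
        ta, tb = p.get(a), p.get(b)
        out[f"ivl_{a}_{b}"] = tb - ta
        out[f"ratio_{a}_{b}"] = tb / ta if ta != 0 else np.nan
    return out


@dataclass(frozen=True)
class RegressionLine:
    """OLS line t_later = slope * t_earlier + intercept for one event pair."""

    pair: tuple[str, str]
    slope: float
    intercept: float
    n_fit: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.n_fit < 2:
            raise ValueError("a regression line needs at least two points")
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("non-finite regression coefficients")


def fit_line(x: np.ndarray, y: np.ndarray, pair: tuple[str, str]) -> RegressionLine:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2:
        raise ValueError(f"{pair}: fewer than 2 complete cases")
    if np.ptp(x) == 0:
        raise ValueError(f"{pair}: zero variance in predictor event — degenerate line")
    res = stats.linregress(x, y)
    return RegressionLine(pair, float(res.slope), float(res.intercept),
                          int(len(x)), float(res.rvalue ** 2))


def fit_dlr_lines(lb_events: pd.DataFrame) -> dict[tuple[str, str], RegressionLine]:
    """Fit the 36 per-pair OLS lines on live-birth embryos only.

    ``lb_events`` must contain only LB-labeled rows, with one column per
    event; incomplete cases are dropped per pair.  Pairs with fewer than two
    complete cases, or a degenerate predictor, yield no line.
    """
    lines: dict[tuple[str, str], RegressionLine] = {}
    for a, b in EVENT_PAIRS:
        if a not in lb_events.columns or b not in lb_events.columns:
            continue
        sub = lb_events[[a, b]].dropna()
        try:
            lines[(a, b)] = fit_line(sub[a].to_numpy(), sub[b].to_numpy(), (a, b))
        except ValueError:
            continue  # flagged by absence
    return lines


def lines_to_json(lines: Mapping[tuple[str, str], RegressionLine], path) -> None:
    """Serialize a fitted line set for reuse at prediction time."""
    payload = [{"pair": list(k), "slope": v.slope, "intercept": v.intercept,
                "n_fit": v.n_fit, "r_squared": v.r_squared}
               for k, v in lines.items()]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def lines_from_json(path) -> dict[tuple[str, str], RegressionLine]:
    with open(path) as fh:
        payload = json.load(fh)
    return {tuple(e["pair"]): RegressionLine(tuple(e["pair"]), e["slope"],
                                             e["intercept"], e["n_fit"],
                                             e["r_squared"])
            for e in payload}


def dlr(p: MorphokineticProfile, line: RegressionLine) -> float:
    """Unsigned shortest distance from the embryo's event pair to the line.

    For the pair (i, j) with fitted line t_j = slope * t_i + intercept, the
    perpendicular distance of the point (t_i, t_j) is
    ``|slope * t_i - t_j + intercept| / sqrt(slope**2 + 1)`` (hours).  Zero
    iff the point lies on the line; NaN if either event is missing.
    """
    a, b = line.pair
    ti, tj = p.get(a), p.get(b)
    return abs(line.slope * ti - tj + line.intercept) / np.sqrt(line.slope ** 2 + 1.0)


def signed_dlr(p: MorphokineticProfile, line: RegressionLine) -> float:
    """Signed variant (positive above the line); excluded from the catalog."""
    a, b = line.pair
    ti, tj = p.get(a), p.get(b)
    return (tj - line.slope * ti - line.intercept) / np.sqrt(line.slope ** 2 + 1.0)


def dlr_features(p: MorphokineticProfile,
                 lines: Mapping[tuple[str, str], RegressionLine]) -> dict[str, float]:
    """DLR for all 36 event pairs; pairs without a fitted line give NaN."""
    out: dict[str, float] = {}
    for pair in EVENT_PAIRS:
        line = lines.get(pair)
        out[f"dlr_{pair[0]}_{pair[1]}"] = dlr(p, line) if line is not None else np.nan
    return out


def morphokinetic_features(p: MorphokineticProfile,
                           lines: Mapping[tuple[str, str], RegressionLine] | None = None,
                           ) -> dict[str, float]:
    """The full 117-value morphokinetic block: 9 events + 36 + 36 + 36 DLR."""
    out = {e: p.get(e) for e in EVENTS}
    out.update(pairwise_intervals_and_ratios(p))
    out.update(dlr_features(p, lines or {}))
    return out
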