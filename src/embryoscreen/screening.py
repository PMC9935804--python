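"""Statistical-distance feature screening and wrapper subset selection.

The screening cascade reduces the 314-feature catalog to a small
non-redundant subset that retains miscarriage-prediction strength:

1. **Statistical distances** — each feature's MC-vs-LB separation is scored
   by the two-sample Kolmogorov-Smirnov p-value and a histogram estimate of
   the Kullback-Leibler divergence KL(MC || LB) in nats.
2. **Threshold grid** — six KS thresholds (spaced +0.05) crossed with three
   KL thresholds (spaced -0.1) define 18 qualified-feature subsets
   (features with p below the KS threshold and KL above the KL threshold).
3. **Monte-Carlo CV scoring** — each subset is scored by the mean validation
   AUC of random-forest and gradient-boosted models over repeated stratified
   90/10 splits; the ten best subsets (by the sum of the two AUCs) are
   united and their features ranked by model importance, keeping the top 8.
4. **Backward elimination** — from the top 8, the feature whose removal
   hurts the combined AUC least is removed stepwise down to one feature; the
   best-scoring subset along the series is retained.
5. **Two-step forward selection** — feature *pairs* from a ranked pool are
   added jointly; the best pair's lower-catalog-index member is kept, for up
   to three cycles, stopping when no pair improves both model families.

All CV splits are train/validation-disjoint within each fold, and every
operation sees only the table it is given — the held-out test partition is
never passed in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, rankdata
from sklearn.model_selection import StratifiedShuffleSplit

from .catalog import CATALOG_INDEX
from .modeling import DEFAULT_SPECS, ModelSpec, auc_score, make_estimator

__all__ = [
    "statistical_distances", "ThresholdGrid", "build_threshold_grid",
    "qualified_subsets", "mc_cv_auc", "SubsetScore", "rank_and_prune",
    "backward_eliminate", "forward_select_two_step", "ScreenConfig",
    "ScreeningResult", "screen_cascade",
]

METADATA_COLUMNS = ("label", "clinic", "transfer_day")

KL_BINS = 20


def _kl_histogram(mc: np.ndarray, lb: np.ndarray, bins: int = KL_BINS) -> float:
    """KL(MC || LB) from a shared equal-width histogram with Laplace pseudocount."""
    lo = min(mc.min(), lb.min())
    hi = max(mc.max(), lb.max())
    if hi == lo:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    p = np.histogram(mc, bins=edges)[0] + 1.0
    q = np.histogram(lb, bins=edges)[0] + 1.0
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def statistical_distances(table: pd.DataFrame, features: Optional[Sequence[str]] = None,
                          label_col: str = "label") -> pd.DataFrame:
    """Per-feature KS p-value and KL divergence between MC and LB embryos.

    Only non-missing values enter; features with fewer than two values in
    either class are skipped (NaN distances, ``skipped`` flag).
    """
    if features is None:
        features = [c for c in table.columns if c not in METADATA_COLUMNS]
    is_mc = table[label_col] == "MC"
    rows = []
    for name in features:
        col = table[name]
        mc = col[is_mc].dropna().to_numpy(dtype=float)
        lb = col[~is_mc].dropna().to_numpy(dtype=float)
        if len(mc) < 2 or len(lb) < 2:
            rows.append({"feature": name, "ks_stat": np.nan, "ks_p": np.nan,
                         "kl": np.nan, "n_mc": len(mc), "n_lb": len(lb), "skipped": True})
            continue
        res = ks_2samp(mc, lb)
        rows.append({"feature": name, "ks_stat": float(res.statistic),
                     "ks_p": float(res.pvalue), "kl": _kl_histogram(mc, lb),
                     "n_mc": len(mc), "n_lb": len(lb), "skipped": False})
    return pd.DataFrame(rows).set_index("feature")


@dataclass(frozen=True)
class ThresholdGrid:
    """6 KS p-value thresholds (+0.05 spacing) x 3 KL thresholds (-0.1 spacing)."""

    ks: tuple[float, ...]
    kl: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ks) != 6 or len(self.kl) != 3:
            raise ValueError("grid requires 6 KS and 3 KL thresholds")
        if not np.allclose(np.diff(self.ks), 0.05):
            raise ValueError("KS thresholds must be spaced by +0.05")
        if not np.allclose(np.diff(self.kl), -0.1):
            raise ValueError("KL thresholds must be spaced by -0.1")


def build_threshold_grid(base_ks: float = 0.05, base_kl: float = 0.25) -> ThresholdGrid:
    """Grid anchored at the base values; 18 (KS, KL) threshold pairs in total."""
    return ThresholdGrid(ks=tuple(base_ks + 0.05 * i for i in range(6)),
                         kl=tuple(base_kl - 0.1 * j for j in range(3)))


def qualified_subsets(distances: pd.DataFrame, grid: ThresholdGrid,
                      ) -> dict[tuple[int, int], tuple[str, ...]]:
    """The 18 qualified subsets: p < KS threshold and KL > KL threshold.

    Keys are (i, j) with i = 1..6 over KS and j = 1..3 over KL.  Empty
    subsets are retained (flagged by their zero length).
    """
    out: dict[tuple[int, int], tuple[str, ...]] = {}
    for i, lam_ks in enumerate(grid.ks, start=1):
        for j, lam_kl in enumerate(grid.kl, start=1):
            sel = distances[(distances["ks_p"] < lam_ks) & (distances["kl"] > lam_kl)]
            out[(i, j)] = tuple(sel.index)
    return out


# ----------------------------------------------------------------- CV scoring

@dataclass
class SubsetScore:
    features: tuple[str, ...]
    mean_auc: dict[str, float]
    fold_aucs: dict[str, np.ndarray]
    importances: dict[str, np.ndarray]        # per family, aligned to features
    n_redrawn: int = 0

    @property
    def combined(self) -> float:
        return float(sum(self.mean_auc.values()))


def _impute_train_medians(Xtr: np.ndarray, Xva: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(all="ignore"):
        med = np.nanmedian(Xtr, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    out = []
    for X in (Xtr, Xva):
        X = X.copy()
        nan = np.isnan(X)
        if nan.any():
            X[nan] = np.take(med, np.nonzero(nan)[1])
        out.append(X)
    return out[0], out[1]


def _fold_indices(y: np.ndarray, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    splitter = StratifiedShuffleSplit(n_splits=n_folds, test_size=0.1, random_state=seed)
    return list(splitter.split(np.zeros((len(y), 1)), y))


def mc_cv_auc(table: pd.DataFrame, subset: Sequence[str], label_col: str = "label",
              n_folds: int = 100, seed: int = 0,
              model_specs: Optional[dict[str, ModelSpec]] = None,
              folds: Optional[list[tuple[np.ndarray, np.ndarray]]] = None,
              dlr_refit=None) -> SubsetScore:
    """Mean validation AUC of each model family over Monte-Carlo 90/10 splits.

    Splits are stratified (a fold whose validation part is single-class would
    be redrawn; stratification prevents it).  Median imputation and, when a
    ``dlr_refit`` hook is supplied, DLR regression lines are fitted on each
    training split only, avoiding leakage into the validation part.

    ``dlr_refit(table, train_index)`` must return a DataFrame of replacement
    columns (indexed like ``table``) recomputed from the fold's training rows.
    """
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    specs = model_specs or DEFAULT_SPECS
    y = (table[label_col] == "MC").to_numpy().astype(int)
    if min((y == 1).sum(), (y == 0).sum()) < 10:
        raise ValueError("need at least 10 embryos per class")
    if folds is None:
        folds = _fold_indices(y, n_folds, seed)
    base_X = table[list(subset)]
    fold_aucs = {fam: np.empty(len(folds)) for fam in specs}
    imps = {fam: np.zeros(len(subset)) for fam in specs}
    for k, (tr, va) in enumerate(folds):
        X = base_X
        if dlr_refit is not None:
            repl = dlr_refit(table, tr)
            cols = [c for c in repl.columns if c in X.columns]
            if cols:
                X = X.copy()
                X[cols] = repl[cols]
        Xtr, Xva = _impute_train_medians(X.to_numpy(float)[tr], X.to_numpy(float)[va])
        for fam, spec in specs.items():
            model = make_estimator(spec, seed=seed + 7919 * k)
            model.fit(Xtr, y[tr])
            fold_aucs[fam][k] = auc_score(y[va], model.predict_proba(Xva)[:, 1])
            imps[fam] += np.asarray(model.feature_importances_, dtype=float)
    return SubsetScore(
        features=tuple(subset),
        mean_auc={fam: float(a.mean()) for fam, a in fold_aucs.items()},
        fold_aucs=fold_aucs,
        importances={fam: v / len(folds) for fam, v in imps.items()})


# ---------------------------------------------------------------- ranking

@dataclass
class RankResult:
    ranked: pd.DataFrame                      # per-feature mean importances + ranks
    top_features: tuple[str, ...]
    pearson: pd.DataFrame
    used_subsets: tuple[tuple[int, int], ...]


def rank_and_prune(scores: dict[tuple[int, int], SubsetScore], table: pd.DataFrame,
                   top_subsets: int = 10, top_k: int = 8) -> RankResult:
    """Union the best subsets, rank features by model importance, keep top k.

    Subsets are ranked by the sum of their RF and GB mean AUCs (ties prefer
    the smaller subset).  Feature importance is each family's native
    importance averaged across all CV experiments whose subset contains the
    feature; ranks are averaged across families, ties broken by catalog
    order.  Returns the top-k features and their Pearson correlation matrix.
    """
    nonempty = {k: s for k, s in scores.items() if len(s.features) > 0}
    if not nonempty:
        raise ValueError("no non-empty scored subsets")
    order = sorted(nonempty, key=lambda k: (-nonempty[k].combined, len(nonempty[k].features), k))
    used = tuple(order[:min(top_subsets, len(order))])

    fams = list(next(iter(nonempty.values())).mean_auc)
    acc: dict[str, dict[str, list[float]]] = {fam: {} for fam in fams}
    for key in used:
        s = nonempty[key]
        for fam in fams:
            for f, v in zip(s.features, s.importances[fam]):
                acc[fam].setdefault(f, []).append(float(v))
    union = sorted({f for key in used for f in nonempty[key].features},
                   key=lambda f: CATALOG_INDEX.get(f, 10 ** 9))
    df = pd.DataFrame(index=union)
    for fam in fams:
        df[f"imp_{fam}"] = [np.mean(acc[fam].get(f, [0.0])) for f in union]
        df[f"rank_{fam}"] = rankdata(-df[f"imp_{fam}"], method="average")
    df["rank_mean"] = df[[f"rank_{fam}" for fam in fams]].mean(axis=1)
    df["catalog_index"] = [CATALOG_INDEX.get(f, 10 ** 9) for f in union]
    df = df.sort_values(["rank_mean", "catalog_index"])
    top = tuple(df.index[:top_k])
    pearson = table[list(top)].corr(method="pearson")
    return RankResult(ranked=df, top_features=top, pearson=pearson, used_subsets=used)


# ----------------------------------------------------- wrapper selection

def backward_eliminate(subset: Sequence[str], table: pd.DataFrame,
                       label_col: str = "label", n_folds: int = 100, seed: int = 0,
                       model_specs: Optional[dict[str, ModelSpec]] = None,
                       ) -> list[SubsetScore]:
    """Stepwise backward elimination from |subset| down to one feature.

    At each step every feature is removed in turn and the removal with the
    smallest negative effect on the combined (RF + GB) mean CV AUC is made
    permanent.  All candidates within a step share the same fold splits
    (common random numbers).  Returns the full score series, largest first.
    """
    current = list(subset)
    if len(current) < 1:
        raise ValueError("subset must be non-empty")
    y = (table[label_col] == "MC").to_numpy().astype(int)
    folds = _fold_indices(y, n_folds, seed)
    series = [mc_cv_auc(table, current, label_col, seed=seed, folds=folds,
                        model_specs=model_specs)]
    while len(current) > 1:
        best: Optional[SubsetScore] = None
        for f in current:  # catalog order; first best wins ties
            cand = [g for g in current if g != f]
            s = mc_cv_auc(table, cand, label_col, seed=seed, folds=folds,
                          model_specs=model_specs)
            if best is None or s.combined > best.combined:
                best = s
        assert best is not None
        series.append(best)
        current = list(best.features)
    return series


def forward_select_two_step(subset: Sequence[str], pool: Sequence[str],
                            table: pd.DataFrame, label_col: str = "label",
                            n_folds: int = 100, seed: int = 0, max_cycles: int = 3,
                            model_specs: Optional[dict[str, ModelSpec]] = None,
                            ) -> tuple[tuple[str, ...], list[dict]]:
    """Two-step forward selection: test feature *pairs*, keep the lower index.

    Per cycle every unordered pair from the pool is added jointly to the
    current subset and scored; the best pair (ties resolved toward the
    lowest catalog indices) is identified and only its lower-catalog-index
    member is retained.  Selection stops early when the best pair fails to
    improve both family AUCs over the current subset, or after
    ``max_cycles`` additions.  Returns (augmented subset, cycle log).
    """
    current = list(subset)
    pool = sorted(set(pool) - set(current), key=lambda f: CATALOG_INDEX.get(f, 10 ** 9))
    if set(pool) & set(current):
        raise ValueError("pool must be disjoint from the subset")
    y = (table[label_col] == "MC").to_numpy().astype(int)
    folds = _fold_indices(y, n_folds, seed)
    log: list[dict] = []
    for _ in range(max_cycles):
        if len(pool) < 2:
            break
        base = mc_cv_auc(table, current, label_col, seed=seed, folds=folds,
                         model_specs=model_specs)
        best_pair: Optional[tuple[str, str]] = None
        best_score: Optional[SubsetScore] = None
        for a_i in range(len(pool)):
            for b_i in range(a_i + 1, len(pool)):
                pair = (pool[a_i], pool[b_i])
                s = mc_cv_auc(table, current + list(pair), label_col, seed=seed,
                              folds=folds, model_specs=model_specs)
                if best_score is None or s.combined > best_score.combined:
                    best_pair, best_score = pair, s
        assert best_pair is not None and best_score is not None
        improves = all(best_score.mean_auc[f] > base.mean_auc[f] for f in base.mean_auc)
        log.append({"pair": best_pair, "pair_auc": best_score.mean_auc,
                    "base_auc": base.mean_auc, "accepted": bool(improves)})
        if not improves:
            break
        keep = min(best_pair, key=lambda f: CATALOG_INDEX.get(f, 10 ** 9))
        current.append(keep)
        pool = [f for f in pool if f != keep]
    return tuple(current), log


# ------------------------------------------------------------- the cascade

@dataclass
class ScreenConfig:
    """Configuration of the full screening cascade."""

    base_ks: float = 0.05
    base_kl: float = 0.25
    n_folds: int = 100
    top_subsets: int = 10
    top_features: int = 8
    forward_pool_size: int = 20
    max_forward_cycles: int = 3
    seed: int = 0


@dataclass
class ScreeningResult:
    distances: pd.DataFrame
    grid: ThresholdGrid
    subsets: dict[tuple[int, int], tuple[str, ...]]
    subset_scores: dict[tuple[int, int], SubsetScore]
    rank: RankResult
    backward_series: list[SubsetScore]
    backward_subset: tuple[str, ...]
    forward_log: list[dict] = field(default_factory=list)
    final_subset: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        def score_dict(s: SubsetScore) -> dict:
            return {"features": list(s.features),
                    "mean_auc": {k: round(v, 10) for k, v in s.mean_auc.items()}}
        return {
            "grid": {"ks": list(self.grid.ks), "kl": list(self.grid.kl)},
            "subsets": {f"{i},{j}": list(v) for (i, j), v in self.subsets.items()},
            "subset_scores": {f"{i},{j}": score_dict(s)
                              for (i, j), s in self.subset_scores.items()},
            "union": list(self.rank.ranked.index),
            "top_features": list(self.rank.top_features),
            "pearson": self.rank.pearson.round(10).to_dict(),
            "backward_series": [score_dict(s) for s in self.backward_series],
            "backward_subset": list(self.backward_subset),
            "forward_log": [{**e, "pair": list(e["pair"])} for e in self.forward_log],
            "final_subset": list(self.final_subset),
            "distances": {k: self.distances[k].round(12).fillna(-1).to_dict()
                          for k in ("ks_p", "kl")},
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def screen_cascade(table: pd.DataFrame, config: ScreenConfig = ScreenConfig(),
                   label_col: str = "label", dlr_refit=None) -> ScreeningResult:
    """Run the full screening cascade on a train/validation table.

    The table must contain only the train/validation partition — the
    held-out test embryos are never passed to any screening operation.
    Identical threshold-grid subsets (the grid is nested by construction)
    are scored once and the score shared.
    """
    cfg = config
    distances = statistical_distances(table, label_col=label_col)
    grid = build_threshold_grid(cfg.base_ks, cfg.base_kl)
    subsets = qualified_subsets(distances, grid)

    cache: dict[tuple[str, ...], SubsetScore] = {}
    scores: dict[tuple[int, int], SubsetScore] = {}
    for key, feats in subsets.items():
        if len(feats) == 0:
            continue
        if feats not in cache:
            cache[feats] = mc_cv_auc(table, feats, label_col, n_folds=cfg.n_folds,
                                     seed=cfg.seed, dlr_refit=dlr_refit)
        scores[key] = cache[feats]

    if not scores:
        raise ValueError("all 18 qualified subsets are empty; relax the base thresholds")

    rank = rank_and_prune(scores, table, top_subsets=cfg.top_subsets,
                          top_k=cfg.top_features)
    series = backward_eliminate(rank.top_features, table, label_col,
                                n_folds=cfg.n_folds, seed=cfg.seed + 1)
    best_i = max(range(len(series)),
                 key=lambda i: (series[i].combined, -len(series[i].features)))
    backward_subset = series[best_i].features

    pool = [f for f in rank.ranked.index
            if f not in backward_subset][:cfg.forward_pool_size]
    final, flog = forward_select_two_step(backward_subset, pool, table, label_col,
                                          n_folds=cfg.n_folds, seed=cfg.seed + 2,
                                          max_cycles=cfg.max_forward_cycles)
    return ScreeningResult(distances=distances, grid=grid, subsets=subsets,
                           subset_scores=scores, rank=rank, backward_series=series,
                           backward_subset=backward_subset, forward_log=flog,
                           final_subset=final)
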