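"""Activity regression: feature linearization, z-standardization, elastic net.

Non-linear features are linearized before regression — categorical/non-linear
numerics via fixed-width binning into indicator parameters (sparse edge bins
collapsed inward), TSS-distance features via RBF-kernel support-vector
regression whose fitted curve value at each position becomes the transformed
parameter, and binary features passed through. All linearized parameters are
z-standardized with training-set statistics and fit with elastic-net linear
regression; the l1/l2 ratio and regularization strength are chosen by
cross-validated grid search. Train/test splits are always by gene.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVR

from .guide_features import roster_hash
from .training_data import ActivityRecord

DEFAULT_C_GRID = tuple(10.0 ** e for e in range(-2, 4))
DEFAULT_GAMMA_GRID = tuple(10.0 ** e for e in range(-7, -1))
DEFAULT_L1_RATIOS = (0.1, 0.25, 0.5, 0.75, 0.9)
DEFAULT_POSITION_WINDOW = (-1500, 1500)


# ---------------------------------------------------------------------------
# binning


@dataclass
class BinnedFeature:
    """Fixed-width binning of one feature into indicator parameters."""

    name: str
    edges: list[float]  # len k+1 for k bins; outermost edges are +-inf
    degenerate: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def param_names(self) -> list[str]:
        return [f"{self.name}__bin{i}" for i in range(self.n_bins)]

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Indicator matrix; rows with NaN are all-zero (flagged missing)."""
        values = np.asarray(values, dtype=float)
        out = np.zeros((len(values), self.n_bins))
        inner = np.asarray(self.edges[1:-1])
        ok = ~np.isnan(values)
        idx = np.searchsorted(inner, values[ok], side="right")
        out[np.flatnonzero(ok), idx] = 1.0
        return out


def bin_feature(
    values: Sequence[float], width: float, sparsity_min: int = 1, name: str = "feature"
) -> BinnedFeature:
    """Fit fixed-width bins over the observed range of ``values``.

    Edge bins holding fewer than ``sparsity_min`` points are merged with
    their neighbor. A constant feature yields a single degenerate bin that
    is flagged for exclusion.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no finite values to bin")
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:
        return BinnedFeature(name, [-np.inf, np.inf], degenerate=True)
    start = np.floor(lo / width) * width
    inner = list(np.arange(start + width, hi + width / 2, width))
    # drop inner edges at/above the max so the top bin is non-empty
    inner = [e for e in inner if e > lo and e <= hi]
    edges = [-np.inf] + inner + [np.inf]

    def counts(es: list[float]) -> np.ndarray:
        idx = np.searchsorted(np.asarray(es[1:-1]), arr, side="right")
        return np.bincount(idx, minlength=len(es) - 1)

    # collapse sparse edge bins inward
    while len(edges) > 2 and counts(edges)[0] < sparsity_min:
        edges.pop(1)
    while len(edges) > 2 and counts(edges)[-1] < sparsity_min:
        edges.pop(-2)
    return BinnedFeature(name, edges, degenerate=len(edges) == 2)


# ---------------------------------------------------------------------------
# SVR position curves


@dataclass
class PositionModel:
    """Fitted distance->activity curve for one TSS edge."""

    window: tuple[float, float]
    gamma: float
    C: float
    support_vectors: np.ndarray  # (n, 1)
    dual_coef: np.ndarray  # (n,)
    intercept: float
    flat_value: Optional[float] = None  # set when training activities were constant

    def predict(self, distances: np.ndarray) -> np.ndarray:
        d = np.asarray(distances, dtype=float).reshape(-1, 1)
        if self.flat_value is not None:
            return np.full(len(d), self.flat_value)
        sq = (d - self.support_vectors.T) ** 2
        return np.exp(-self.gamma * sq) @ self.dual_coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "window": list(self.window),
            "gamma": self.gamma,
            "C": self.C,
            "support_vectors": self.support_vectors.ravel().tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "flat_value": self.flat_value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PositionModel":
        return cls(
            window=tuple(d["window"]),
            gamma=d["gamma"],
            C=d["C"],
            support_vectors=np.asarray(d["support_vectors"], dtype=float).reshape(-1, 1),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=d["intercept"],
            flat_value=d["flat_value"],
        )


def fit_position_svr(
    distances: Sequence[float],
    activities: Sequence[float],
    window: tuple[float, float] = DEFAULT_POSITION_WINDOW,
    cv_folds: int = 3,
    seed: int = 0,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    min_train: int = 200,
) -> PositionModel:
    """Grid-searched RBF SVR of activity on signed TSS distance."""
    d = np.asarray(distances, dtype=float)
    y = np.asarray(activities, dtype=float)
    keep = ~np.isnan(d) & ~np.isnan(y) & (d >= window[0]) & (d <= window[1])
    d, y = d[keep], y[keep]
    if len(d) < min_train:
        raise ValueError(f"need >= {min_train} training pairs in window, got {len(d)}")
    if np.allclose(y, y[0]):
        warnings.warn("constant activities; returning flat position model", stacklevel=2)
        return PositionModel(window, 0.0, 0.0, np.zeros((0, 1)), np.zeros(0),
                             0.0, flat_value=float(y[0]))
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVR(kernel="rbf"),
        {"C": list(C_grid), "gamma": list(gamma_grid)},
        cv=cv,
        scoring="neg_mean_squared_error",
        n_jobs=1,
    )
    search.fit(d.reshape(-1, 1), y)
    best: SVR = search.best_estimator_
    return PositionModel(
        window=window,
        gamma=float(best.gamma),
        C=float(best.C),
        support_vectors=np.asarray(best.support_vectors_, dtype=float),
        dual_coef=np.asarray(best.dual_coef_, dtype=float).ravel(),
        intercept=float(best.intercept_[0]),
    )


# ---------------------------------------------------------------------------
# linearization recipe


@dataclass
class Linearizer:
    """Fitted recipe turning raw features into linear parameters.

    ``recipe`` maps feature name -> ("binary",) | ("passthrough",) |
    ("bin", width, sparsity_min) | ("position", window). Features absent
    from the recipe are passed through.
    """

    recipe: dict[str, tuple]
    binned: dict[str, BinnedFeature] = field(default_factory=dict)
    position_models: dict[str, PositionModel] = field(default_factory=dict)
    fill_values: dict[str, float] = field(default_factory=dict)
    param_names_: list[str] = field(default_factory=list)

    def fit(
        self,
        features: pd.DataFrame,
        activity: np.ndarray,
        seed: int = 0,
        svr_kwargs: Optional[dict] = None,
    ) -> "Linearizer":
        svr_kwargs = svr_kwargs or {}
        self.param_names_ = []
        for name in features.columns:
            kind = self.recipe.get(name, ("passthrough",))
            col = features[name].to_numpy(dtype=float)
            if kind[0] == "bin":
                bf = bin_feature(col, width=kind[1], sparsity_min=kind[2], name=name)
                if bf.degenerate or bf.n_bins < 2:
                    continue  # constant feature: no information
                self.binned[name] = bf
                self.param_names_ += bf.param_names()
            elif kind[0] == "position":
                valid = ~np.isnan(col)
                if valid.sum() == 0:
                    continue
                try:
                    pm = fit_position_svr(
                        col[valid], activity[valid], window=kind[1], seed=seed,
                        **svr_kwargs,
                    )
                except ValueError as exc:
                    warnings.warn(f"position feature {name} dropped: {exc}",
                                  stacklevel=2)
                    continue
                self.position_models[name] = pm
                tr = self._position_param(name, col)
                self.fill_values[name] = float(np.nanmean(tr))
                self.param_names_.append(f"{name}__svr")
            else:  # binary / passthrough
                finite = col[~np.isnan(col)]
                if finite.size == 0 or np.allclose(finite, finite[0] if finite.size else 0):
                    continue  # constant or all-missing: no information
                self.fill_values[name] = float(np.nanmean(col))
                self.param_names_.append(name)
        return self

    def _position_param(self, name: str, col: np.ndarray) -> np.ndarray:
        pm = self.position_models[name]
        out = np.full(len(col), np.nan)
        valid = ~np.isnan(col)
        clipped = np.clip(col[valid], pm.window[0], pm.window[1])
        out[valid] = pm.predict(clipped)
        return out

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}
        for name in features.columns:
            kind = self.recipe.get(name, ("passthrough",))
            col = features[name].to_numpy(dtype=float)
            if kind[0] == "bin":
                if name not in self.binned:
                    continue
                mat = self.binned[name].transform(col)
                for i, pname in enumerate(self.binned[name].param_names()):
                    cols[pname] = mat[:, i]
            elif kind[0] == "position":
                if name not in self.position_models:
                    continue
                tr = self._position_param(name, col)
                tr[np.isnan(tr)] = self.fill_values[name]
                cols[f"{name}__svr"] = tr
            else:
                if name not in self.fill_values:
                    continue
                filled = np.where(np.isnan(col), self.fill_values[name], col)
                cols[name] = filled
        return pd.DataFrame(cols, index=features.index)[self.param_names_]


def default_recipe(feature_names: Sequence[str]) -> dict[str, tuple]:
    """Linearization kinds keyed off the standard roster's naming scheme."""
    recipe: dict[str, tuple] = {}
    for name in feature_names:
        if name.startswith("dist_"):
            recipe[name] = ("position", DEFAULT_POSITION_WINDOW)
        elif name.startswith(("base_", "dinuc_")):
            recipe[name] = ("binary",)
        elif name.startswith(("count_", "homopolymer_", "paired_")):
            recipe[name] = ("bin", 1.0, 5)
        elif name == "gc_fraction":
            recipe[name] = ("bin", 0.1, 5)
        elif name.startswith("mfe_"):
            recipe[name] = ("bin", 2.0, 5)
        else:  # protospacer_length, chromatin_* and anything unrecognized
            recipe[name] = ("passthrough",)
    return recipe


# ---------------------------------------------------------------------------
# the model


class RosterMismatchError(ValueError):
    pass


@dataclass
class ActivityModel:
    roster_hash: str
    feature_names: list[str]
    linearizer: Linearizer
    means: np.ndarray
    sds: np.ndarray
    coef: np.ndarray
    intercept: float
    l1_ratio: float
    alpha: float
    train_genes: list[str] = field(default_factory=list)
    test_genes: list[str] = field(default_factory=list)

    @property
    def param_names(self) -> list[str]:
        return self.linearizer.param_names_

    def _design(self, features: pd.DataFrame) -> np.ndarray:
        if roster_hash(list(features.columns)) != self.roster_hash:
            raise RosterMismatchError(
                "feature roster does not match the roster the model was trained on"
            )
        params = self.linearizer.transform(features).to_numpy(dtype=float)
        return (params - self.means) / self.sds

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self._design(features) @ self.coef + self.intercept

    def param_contributions(self, features: pd.DataFrame) -> pd.DataFrame:
        """Per-sgRNA coefficient-weighted standardized parameters."""
        z = self._design(features)
        return pd.DataFrame(z * self.coef, index=features.index, columns=self.param_names)

    def to_json(self) -> str:
        doc = {
            "format_version": 1,
            "roster_hash": self.roster_hash,
            "feature_names": self.feature_names,
            "recipe": {k: list(v) for k, v in self.linearizer.recipe.items()},
            "binned": {
                k: {"edges": [float(e) for e in b.edges], "degenerate": b.degenerate}
                for k, b in self.linearizer.binned.items()
            },
            "position_models": {
                k: pm.to_dict() for k, pm in self.linearizer.position_models.items()
            },
            "fill_values": self.linearizer.fill_values,
            "param_names": self.linearizer.param_names_,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "l1_ratio": self.l1_ratio,
            "alpha": self.alpha,
            "train_genes": self.train_genes,
            "test_genes": self.test_genes,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "ActivityModel":
        doc = json.loads(text)
        lin = Linearizer(recipe={k: tuple(v) for k, v in doc["recipe"].items()})
        lin.binned = {
            k: BinnedFeature(k, [float(e) for e in b["edges"]], b["degenerate"])
            for k, b in doc["binned"].items()
        }
        lin.position_models = {
            k: PositionModel.from_dict(d) for k, d in doc["position_models"].items()
        }
        lin.fill_values = doc["fill_values"]
        lin.param_names_ = doc["param_names"]
        return cls(
            roster_hash=doc["roster_hash"],
            feature_names=doc["feature_names"],
            linearizer=lin,
            means=np.asarray(doc["means"], dtype=float),
            sds=np.asarray(doc["sds"], dtype=float),
            coef=np.asarray(doc["coef"], dtype=float),
            intercept=doc["intercept"],
            l1_ratio=doc["l1_ratio"],
            alpha=doc["alpha"],
            train_genes=doc["train_genes"],
            test_genes=doc["test_genes"],
        )


def gene_split(
    genes: Sequence[str], test_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Deterministic gene-wise train/test split."""
    unique = sorted(set(genes))
    rng = np.random.default_rng(seed)
    rng.shuffle(unique)
    n_test = max(1, int(round(len(unique) * test_fraction)))
    test = sorted(unique[:n_test])
    train = sorted(unique[n_test:])
    if set(train) & set(test):
        raise ValueError("train and test gene sets overlap")
    return train, test


def fit_activity_model(
    features: pd.DataFrame,
    records: Sequence[ActivityRecord],
    test_fraction: float = 0.2,
    seed: int = 0,
    recipe: Optional[dict[str, tuple]] = None,
    l1_ratios: Sequence[float] = DEFAULT_L1_RATIOS,
    n_alphas: int = 30,
    cv_folds: int = 5,
    svr_kwargs: Optional[dict] = None,
) -> ActivityModel:
    """Fit the full linearize -> standardize -> elastic-net pipeline.

    ``features`` is indexed by sgRNA id; ``records`` supply activity scores
    and the gene labels used for the gene-wise split.
    """
    rec_by_id = {r.sgrna_id: r for r in records}
    ids = [i for i in features.index if i in rec_by_id]
    if not ids:
        raise ValueError("no overlap between feature rows and activity records")
    feats = features.loc[ids]
    activity = np.array([rec_by_id[i].activity_score for i in ids])
    genes = np.array([rec_by_id[i].gene for i in ids])

    train_genes, test_genes = gene_split(genes, test_fraction, seed)
    train_mask = np.isin(genes, train_genes)

    recipe = recipe if recipe is not None else default_recipe(list(feats.columns))
    lin = Linearizer(recipe=recipe).fit(
        feats[train_mask], activity[train_mask], seed=seed, svr_kwargs=svr_kwargs
    )
    params_train = lin.transform(feats[train_mask]).to_numpy(dtype=float)
    means = params_train.mean(axis=0)
    sds = params_train.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0  # degenerate parameters contribute 0 after centering
    z_train = (params_train - means) / sds

    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    enet_cv = ElasticNetCV(
        l1_ratio=list(l1_ratios), alphas=n_alphas, cv=cv, max_iter=5000, n_jobs=1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enet_cv.fit(z_train, activity[train_mask])
    final = ElasticNet(
        alpha=enet_cv.alpha_, l1_ratio=enet_cv.l1_ratio_, max_iter=10000
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(z_train, activity[train_mask])

    return ActivityModel(
        roster_hash=roster_hash(list(feats.columns)),
        feature_names=list(feats.columns),
        linearizer=lin,
        means=means,
        sds=sds,
        coef=np.asarray(final.coef_, dtype=float),
        intercept=float(final.intercept_),
        l1_ratio=float(enet_cv.l1_ratio_),
        alpha=float(enet_cv.alpha_),
        train_genes=list(train_genes),
        test_genes=list(test_genes),
    )


def predict_activity(model: ActivityModel, features: pd.DataFrame) -> pd.Series:
    """Predicted activity scores; pure function of (model, features)."""
    return pd.Series(model.predict(features), index=features.index, name="predicted_score")


# ---------------------------------------------------------------------------
# evaluation


def roc_curve_points(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(fpr, tpr) over the full ranking, ties handled as score plateaus."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or (~labels).all():
        raise ValueError("ROC undefined for single-class labels")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    tps = np.cumsum(l)
    fps = np.cumsum(~l)
    # keep only threshold boundaries (last index of each tie block)
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tpr = np.r_[0.0, tps[distinct] / labels.sum()]
    fpr = np.r_[0.0, fps[distinct] / (~labels).sum()]
    return fpr, tpr


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    fpr, tpr = roc_curve_points(labels, scores)
    return float(np.trapezoid(tpr, fpr))


def evaluate_model(
    model: ActivityModel,
    features: pd.DataFrame,
    records: Sequence[ActivityRecord],
    active_threshold: float = 0.75,
) -> dict:
    """ROC of predicted scores against the highly-active label."""
    rec_by_id = {r.sgrna_id: r for r in records}
    ids = [i for i in features.index if i in rec_by_id]
    feats = features.loc[ids]
    activity = np.array([rec_by_id[i].activity_score for i in ids])
    scores = model.predict(feats)
    labels = activity > active_threshold
    fpr, tpr = roc_curve_points(labels, scores)
    return {
        "auc": float(np.trapezoid(tpr, fpr)),
        "fpr": fpr,
        "tpr": tpr,
        "n": len(ids),
        "n_active": int(labels.sum()),
    }


def default_categories(param_names: Sequence[str]) -> dict[str, str]:
    cats = {}
    for p in param_names:
        if p.startswith("dist_"):
            cats[p] = "position"
        elif p.startswith(("mfe_", "paired_")):
            cats[p] = "rna_structure"
        elif p.startswith("chromatin_"):
            cats[p] = "chromatin"
        else:
            cats[p] = "sequence"
    return cats


def feature_category_contribution(
    model: ActivityModel,
    features: pd.DataFrame,
    categories: Optional[Mapping[str, str]] = None,
) -> pd.Series:
    """Spread (95th - 5th percentile) of per-category summed weighted params."""
    categories = categories or default_categories(model.param_names)
    contrib = model.param_contributions(features)
    sums: dict[str, np.ndarray] = {}
    for pname in contrib.columns:
        cat = categories.get(pname, "other")
        sums.setdefault(cat, np.zeros(len(contrib)))
        sums[cat] += contrib[pname].to_numpy()
    return pd.Series(
        {cat: float(np.percentile(v, 95) - np.percentile(v, 5)) for cat, v in sums.items()}
    ).sort_index()
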