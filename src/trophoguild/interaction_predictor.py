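"""Pairwise consumer-prey interaction prediction from phylogeny and size.

Every (consumer species, prey group) pair is a binary instance: the
positive label means the prey group occurs in the species' pooled diet
(above a configurable presence threshold). Features are the species'
phylogenetic eigenvector coordinates (principal coordinates of the
double-centered patristic distance matrix), ln(maximum body size) and a
one-hot encoding of the prey group. Three base learners (two gradient
boosting variants and a random forest, 2,000 trees each by default) are
calibrated by 10-fold cross-validation and combined by a logistic
super-learner fitted on out-of-fold predictions only. Performance is
reported as AUC and the true skill statistic (TSS = sensitivity +
specificity - 1) at a threshold maximizing sensitivity + specificity on
calibration predictions; transferability is assessed by holding out an
entire sampling region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from ._phylo import PhyloArrays
from .core_data import PREY_GROUPS, DietMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "phylo_eigenvectors",
    "build_interaction_table",
    "assemble_features",
    "InteractionModel",
    "EvalReport",
    "fit_ensemble",
    "rank_auc",
    "evaluate",
    "leave_region_out",
    "predict_global",
]


# ----------------------------------------------------------------------
# Features
# ----------------------------------------------------------------------

def phylo_eigenvectors(tree: dendropy.Tree | PhyloArrays,
                       n_axes: int | None = None,
                       var_fraction: float = 0.95) -> pd.DataFrame:
    """Phylogenetic eigenvector map: principal coordinates of the tips.

    The patristic distance matrix is double-centered (Gower) and
    eigendecomposed; axes with positive eigenvalues are kept, ordered
    by descending eigenvalue, and truncated either to ``n_axes`` or to
    the smallest set explaining ``var_fraction`` of the positive-
    eigenvalue variance. Squared Euclidean distances over the full
    positive set reproduce the patristic distances.
    """
    arr = tree if isinstance(tree, PhyloArrays) else PhyloArrays.from_dendropy(tree)
    D = arr.patristic_distances()
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D @ J
    B = (B + B.T) / 2.0
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0.0) * 1e-10
    vals, vecs = vals[pos], vecs[:, pos]
    coords = vecs * np.sqrt(vals)[None, :]
    if n_axes is not None:
        keep = min(n_axes, coords.shape[1])
    else:
        frac = np.cumsum(vals) / vals.sum()
        keep = int(np.searchsorted(frac, var_fraction) + 1)
    cols = [f"PEM{i + 1}" for i in range(coords.shape[1])]
    df = pd.DataFrame(coords, index=arr.labels, columns=cols)
    df.attrs["eigenvalues"] = vals
    return df.iloc[:, :keep]


def build_interaction_table(diet: DietMatrix, presence_threshold: float = 0.0,
                            region: str | None = None) -> pd.DataFrame:
    """Binary (species x prey group) interaction instances from a diet matrix.

    The full cartesian product of consumers and the 38 prey groups is
    labeled 1 where the pooled diet proportion exceeds
    ``presence_threshold`` and 0 elsewhere.
    """
    mat = diet.matrix.reindex(columns=list(PREY_GROUPS), fill_value=0.0)
    rows = []
    for sp in mat.index:
        species = sp.split("@", 1)[0]
        for grp in PREY_GROUPS:
            rows.append({
                "species": species, "consumer": sp, "prey_group": grp,
                "label": int(mat.at[sp, grp] > presence_threshold),
            })
    out = pd.DataFrame(rows)
    if region is not None:
        out["region"] = region
    return out


def assemble_features(table: pd.DataFrame, pem: pd.DataFrame,
                      attrs: pd.DataFrame) -> pd.DataFrame:
    """Join eigenvector, size and one-hot prey-group features onto pairs."""
    missing = sorted(set(table["species"]) - set(pem.index))
    if missing:
        raise ValueError(f"species without eigenvector coordinates: {missing[:5]}")
    X = pem.loc[table["species"]].reset_index(drop=True)
    X["ln_size"] = np.log(attrs.loc[table["species"], "max_size_cm"]
                          .to_numpy(float))
    onehot = pd.get_dummies(pd.Categorical(table["prey_group"],
                                           categories=list(PREY_GROUPS)),
                            prefix="prey", dtype=float).reset_index(drop=True)
    return pd.concat([X, onehot], axis=1)


# ----------------------------------------------------------------------
# Ensemble
# ----------------------------------------------------------------------

def _base_learners(n_trees: int, seed: int) -> dict:
    from lightgbm import LGBMClassifier
    from xgboost import XGBClassifier

    return {
        "xgb": XGBClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1,
            tree_method="hist", verbosity=0, eval_metric="logloss"),
        "gbm": LGBMClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1,
            verbose=-1, deterministic=True, force_row_wise=True),
        "rf": RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1),
    }


def _logit(p: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    p = np.clip(p, eps, 1 - eps)
    return np.log(p / (1 - p))


@dataclass
class InteractionModel:
    """Three base learners plus a logistic super-learner over their
    out-of-fold predictions (logit scale, so the stack can reproduce any
    single base learner exactly)."""

    learners: dict
    meta: LogisticRegression
    oof: pd.DataFrame            # out-of-fold base + stacked predictions
    y_train: np.ndarray
    feature_names: list[str]
    threshold: float = field(default=float("nan"))
    n_trees: int = 2000
    seed: int = 0

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        base = np.column_stack([
            self.learners[name].predict_proba(X[self.feature_names])[:, 1]
            for name in sorted(self.learners)
        ])
        return self.meta.predict_proba(_logit(base))[:, 1]

    def base_log_losses(self) -> dict[str, float]:
        out = {name: float(log_loss(self.y_train, self.oof[name]))
               for name in sorted(self.learners)}
        out["stacked"] = float(log_loss(self.y_train, self.oof["stacked"]))
        return out


def fit_ensemble(X: pd.DataFrame, y: np.ndarray, folds: int = 10,
                 n_trees: int = 2000, seed: int = 0) -> InteractionModel:
    """Fit the stacked ensemble.

    Base learners are cross-validated with a stratified ``folds``-fold
    plan; the logistic super-learner sees only out-of-fold predictions
    (no leakage), and the final base learners are refit on all data.
    The classification threshold maximizing sensitivity + specificity
    is chosen on the stacked out-of-fold predictions.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit the ensemble")
    names = sorted(_base_learners(1, 0))
    oof = pd.DataFrame(index=np.arange(len(y)), columns=names, dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr_idx, te_idx in skf.split(X, y):
        fold_learners = _base_learners(n_trees, seed)
        for name in names:
            fold_learners[name].fit(X.iloc[tr_idx], y[tr_idx])
            oof.loc[te_idx, name] = \
                fold_learners[name].predict_proba(X.iloc[te_idx])[:, 1]
    meta = LogisticRegression(C=1e6, max_iter=2000)
    meta.fit(_logit(oof[names].to_numpy()), y)
    oof["stacked"] = meta.predict_proba(_logit(oof[names].to_numpy()))[:, 1]
    learners = _base_learners(n_trees, seed)
    for name in names:
        learners[name].fit(X, y)
    model = InteractionModel(
        learners=learners, meta=meta, oof=oof, y_train=y,
        feature_names=list(X.columns), n_trees=n_trees, seed=seed)
    model.threshold = _max_tss_threshold(y, oof["stacked"].to_numpy())
    return model


# ----------------------------------------------------------------------
# Evaluation
# ----------------------------------------------------------------------

def rank_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic (tie-aware)."""
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _max_tss_threshold(y: np.ndarray, scores: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity on given scores."""
    order = np.argsort(scores)[::-1]
    ys = np.asarray(y)[order]
    ss = np.asarray(scores)[order]
    n1, n0 = ys.sum(), (1 - ys).sum()
    tp = np.cumsum(ys)
    fp = np.cumsum(1 - ys)
    sens = tp / n1
    spec = 1 - fp / n0
    j = sens + spec
    # candidate thresholds sit between distinct consecutive scores
    best = int(np.argmax(j))
    thr = ss[best] if best == len(ss) - 1 else (ss[best] + ss[best + 1]) / 2
    return float(thr)


@dataclass
class EvalReport:
    auc: float
    tss: float
    sensitivity: float
    specificity: float
    false_positive_rate: float
    threshold: float

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc, "tss": self.tss,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "false_positive_rate": self.false_positive_rate,
            "threshold": self.threshold,
        }


def evaluate(scores: np.ndarray, y: np.ndarray,
             threshold: float | None = None) -> EvalReport:
    """AUC, TSS and error rates of predicted probabilities.

    ``threshold`` should come from calibration predictions (e.g. the
    model's stored max-TSS threshold), never from the test labels; when
    omitted it is derived from the scores being evaluated, which is only
    appropriate for calibration reporting.
    """
    y = np.asarray(y, dtype=int)
    auc = rank_auc(y, scores)
    if threshold is None:
        threshold = _max_tss_threshold(y, scores)
    pred = np.asarray(scores) > threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return EvalReport(auc=auc, tss=sens + spec - 1.0, sensitivity=sens,
                      specificity=spec, false_positive_rate=fp / (fp + tn),
                      threshold=float(threshold))


def leave_region_out(tables: dict[str, pd.DataFrame], held_out: str,
                     pem: pd.DataFrame, attrs: pd.DataFrame,
                     folds: int = 10, n_trees: int = 2000,
                     seed: int = 0) -> tuple[EvalReport, InteractionModel]:
    """Train on all regions but one; evaluate on the held-out region.

    The TSS threshold is chosen on the training regions' out-of-fold
    predictions, never on the held-out data.
    """
    if held_out not in tables:
        raise ValueError(f"unknown region {held_out!r}; have {sorted(tables)}")
    if len(tables) < 2:
        raise ValueError("need at least 2 regions")
    train = pd.concat([t for r, t in tables.items() if r != held_out],
                      ignore_index=True)
    test = tables[held_out].reset_index(drop=True)
    X_train = assemble_features(train, pem, attrs)
    X_test = assemble_features(test, pem, attrs)
    model = fit_ensemble(X_train, train["label"].to_numpy(), folds=folds,
                         n_trees=n_trees, seed=seed)
    scores = model.predict(X_test)
    report = evaluate(scores, test["label"].to_numpy(),
                      threshold=model.threshold)
    return report, model


def predict_global(model: InteractionModel, species: pd.DataFrame,
                   pem: pd.DataFrame) -> pd.DataFrame:
    """Species x 38 prey-group interaction probability table.

    Species without eigenvector coordinates (off-tree) are skipped with
    a warning.
    """
    known = [sp for sp in species.index if sp in pem.index]
    skipped = sorted(set(species.index) - set(known))
    if skipped:
        logger.warning("skipping %d species not on the tree: %s",
                       len(skipped), skipped[:5])
    pairs = pd.DataFrame(
        [(sp, grp) for sp in known for grp in PREY_GROUPS],
        columns=["species", "prey_group"])
    X = assemble_features(pairs, pem, species)
    probs = model.predict(X)
    out = pd.DataFrame(probs.reshape(len(known), len(PREY_GROUPS)),
                       index=known, columns=list(PREY_GROUPS))
    return out
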