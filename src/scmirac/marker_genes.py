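"""Rank genes separating a chosen set of clusters with gradient-boosted trees.

A gene's importance is the number of times it is used as an inner (split)
node across the decision trees of an XGBoost classifier trained to tell the
selected clusters apart.  To damp stochastic training effects, the
classifier is refit over bootstrap rounds: cells are resampled within each
cluster, the gene column order is randomly permuted (feature shuffling),
and the model is trained with stratified cross-validation; importances are
aggregated as mean and standard deviation over rounds.  The output is a
ranking for inspection — deliberately not a per-gene p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix_core import CountMatrix

DEFAULT_BOOSTER_PARAMS = {
    "max_depth": 4,
    "learning_rate": 0.3,
    "n_estimators": 100,
    "early_stopping_rounds": 10,
}

__all__ = ["ImportanceTable", "rank_separating_genes", "gene_panels"]


@dataclass
class ImportanceTable:
    """Per-gene importance summary over bootstrap rounds.

    ``table`` is indexed by gene id with columns mean_importance,
    sd_importance, bootstrap_count and rank (1 = most important).
    ``cv_accuracy`` is the mean held-out fold accuracy, reported so a
    no-signal comparison (accuracy near chance) is visible next to the
    ranking.
    """

    table: pd.DataFrame
    selected_clusters: tuple
    cv_accuracy: float
    boosters: list = field(default_factory=list, repr=False)


def _values_labels(X, labels):
    A = X.toarray() if hasattr(X, "toarray") else np.asarray(X, dtype=float)
    lab = np.asarray(getattr(labels, "labels", labels)).ravel()
    if lab.size != A.shape[0]:
        raise ValueError("labels length does not match number of cells")
    return A, lab


def rank_separating_genes(X, labels, clusters, n_boot: int = 30, cv_folds: int = 5,
                          booster_params: dict | None = None, seed: int | None = None,
                          keep_boosters: bool = False) -> ImportanceTable:
    """Importance ranking of genes separating the given clusters.

    Per bootstrap round: stratified resampling with replacement, an
    independent random permutation of gene columns, then one booster per
    stratified CV fold (early-stopped on the held-out fold); per-gene split
    counts are summed across folds and mapped back to the original gene
    order.  Deterministic given ``seed``.
    """
    import xgboost as xgb
    from sklearn.model_selection import StratifiedKFold

    A, lab = _values_labels(X, labels)
    clusters = tuple(clusters)
    if len(clusters) < 2:
        raise ValueError("select at least 2 clusters to compare")
    sel = np.isin(lab, clusters)
    A, lab = A[sel], lab[sel]
    for c in clusters:
        n_c = int((lab == c).sum())
        if n_c < cv_folds:
            raise ValueError(f"cluster {c!r} has {n_c} cells, fewer than cv_folds={cv_folds}")
    gene_ids = (np.asarray(X.gene_ids) if isinstance(X, CountMatrix)
                else np.array([f"gene_{j}" for j in range(A.shape[1])], dtype=object))
    code = {c: i for i, c in enumerate(clusters)}
    y = np.array([code[v] for v in lab])
    n, m = A.shape
    params = dict(DEFAULT_BOOSTER_PARAMS, **(booster_params or {}))
    early = params.pop("early_stopping_rounds", 10)
    n_classes = len(clusters)

    rng = np.random.default_rng(seed)
    per_round = np.zeros((n_boot, m))
    accs = []
    boosters = []
    for b in range(n_boot):
        perm = rng.permutation(m)
        Xb, yb = A[:, perm], y
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        counts = np.zeros(m)
        for train_orig, val in skf.split(Xb, yb):
            # bootstrap the training cells only (stratified, with
            # replacement); the held-out fold stays untouched so the
            # early-stopping signal and accuracy are honest
            train = np.concatenate([
                rng.choice(train_orig[yb[train_orig] == ci],
                           size=int((yb[train_orig] == ci).sum()), replace=True)
                for ci in range(n_classes)
            ])
            clf = xgb.XGBClassifier(
                objective="multi:softprob" if n_classes > 2 else "binary:logistic",
                num_class=n_classes if n_classes > 2 else None,
                eval_metric="mlogloss" if n_classes > 2 else "logloss",
                early_stopping_rounds=early, n_jobs=1, verbosity=0,
                random_state=int(rng.integers(2 ** 31)), **params,
            )
            clf.fit(Xb[train], yb[train], eval_set=[(Xb[val], yb[val])], verbose=False)
            # count splits only in the cross-validated (early-stopped) model;
            # trees grown during the patience window are discarded
            booster = clf.get_booster()[: clf.best_iteration + 1]
            score = booster.get_score(importance_type="weight")
            for feat, cnt in score.items():
                counts[int(feat[1:])] += cnt
            accs.append(float((clf.predict(Xb[val]) == yb[val]).mean()))
            if keep_boosters:
                boosters.append(booster)
        inv = np.empty(m, dtype=np.int64)
        inv[perm] = np.arange(m)
        per_round[b] = counts[inv]

    mean_imp = per_round.mean(axis=0)
    sd_imp = per_round.std(axis=0)
    order = np.argsort(-mean_imp, kind="stable")
    rank = np.empty(m, dtype=np.int64)
    rank[order] = np.arange(1, m + 1)
    table = pd.DataFrame({
        "mean_importance": mean_imp,
        "sd_importance": sd_imp,
        "bootstrap_count": n_boot,
        "rank": rank,
    }, index=pd.Index(gene_ids, name="gene"))
    return ImportanceTable(table=table.sort_values("rank"),
                           selected_clusters=clusters,
                           cv_accuracy=float(np.mean(accs)),
                           boosters=boosters)


def gene_panels(table: ImportanceTable, top_n: int, X=None, labels=None) -> pd.DataFrame:
    """Top genes in rank order, with per-cluster means and log2 fold changes.

    Fold change uses pseudocount 1; for two compared clusters it is
    log2((mean_a + 1)/(mean_b + 1)); for more, the top-expressing cluster
    against the mean of the others.  Expression columns require ``X`` and
    ``labels``.
    """
    tab = table.table
    if top_n > len(tab):
        raise ValueError(f"top_n={top_n} exceeds number of genes {len(tab)}")
    panel = tab.iloc[:top_n].copy()
    if X is not None and labels is not None and top_n > 0:
        A, lab = _values_labels(X, labels)
        gene_ids = list(np.asarray(X.gene_ids) if isinstance(X, CountMatrix)
                        else [f"gene_{j}" for j in range(A.shape[1])])
        col_of = {g: j for j, g in enumerate(gene_ids)}
        cl = table.selected_clusters
        means = {c: A[lab == c] for c in cl}
        for c in cl:
            panel[f"mean_expr_{c}"] = [means[c][:, col_of[g]].mean() for g in panel.index]
        if len(cl) == 2:
            a, b = cl
            panel["log2_fold_change"] = np.log2(
                (panel[f"mean_expr_{a}"] + 1) / (panel[f"mean_expr_{b}"] + 1))
        else:
            expr = panel[[f"mean_expr_{c}" for c in cl]].to_numpy()
            top = expr.max(axis=1)
            rest = (expr.sum(axis=1) - top) / (len(cl) - 1)
            panel["log2_fold_change"] = np.log2((top + 1) / (rest + 1))
    return panel
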