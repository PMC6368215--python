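"""QSAR and ligand-based virtual-screening evaluation harness.

QSAR follows a nested cross-validation design: 5 outer folds (random or
leave-one-cluster-out from K-means on MACCS keys), an inner grid search on
the training folds only, feature standardization fitted inside the training
folds, and r^2 / ROC AUC as the outer metrics. Virtual screening follows the
group-fusion protocol: per repetition five random query actives, every other
compound scored by its maximum (by default) similarity to the queries, ROC
AUC of remaining actives versus decoys, averaged over 50 repetitions;
descriptor sets are compared across targets with the two-sided Wilcoxon
signed-rank test.

Any vector-valued molecule featurization works: the harness only consumes a
matrix whose rows align with the molecule list (the fingerprint plug-in
contract). ECFP-family count fingerprints and MACCS keys are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .chem_prep import MoleculeRecord
from .inference import standardize_columns
from .synthetic import QsarTask, VsTarget

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def ecfc4_counts(mol: Chem.Mol) -> np.ndarray:
    """Hashed circular count fingerprint, radius 2 (diameter 4)."""
    return _MORGAN.GetCountFingerprintAsNumPy(mol).astype(np.float64)


def maccs_bits(mol: Chem.Mol) -> np.ndarray:
    """167-bit MACCS structural keys as a 0/1 vector."""
    fp = MACCSkeys.GenMACCSKeys(mol)
    return np.array(fp, dtype=np.float64)


def featurize(records: Sequence[MoleculeRecord],
              fn: Callable[[Chem.Mol], np.ndarray]) -> np.ndarray:
    return np.stack([fn(r.mol()) for r in records])


def tanimoto_counts(a: np.ndarray, b: np.ndarray) -> float:
    """Min/max generalization of Tanimoto similarity for count vectors."""
    mx = np.maximum(a, b).sum()
    if mx == 0:
        return 1.0
    return float(np.minimum(a, b).sum() / mx)


def roc_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Rank (Mann-Whitney) ROC AUC; tied scores contribute 1/2."""
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def cluster_split(molecules: Sequence[MoleculeRecord], K: int = 5,
                  seed: int = 0, max_retries: int = 10) -> np.ndarray:
    """Fold assignment from K-means (K clusters) on MACCS keys.

    Folds are the clusters themselves (leave-one-cluster-out CV), so fold
    sizes are unequal by construction.
    """
    if len(molecules) < K:
        raise ValueError("need at least K molecules")
    X = featurize(molecules, maccs_bits)
    for attempt in range(max_retries):
        km = KMeans(n_clusters=K, n_init=10, random_state=seed + attempt)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) == K:
            return labels
    raise RuntimeError("K-means produced an empty cluster in every retry")


_SVM_GRID = {"model__C": [0.1, 1.0, 10.0, 100.0],
             "model__gamma": ["scale", "auto"]}


def run_qsar(task: QsarTask, X: np.ndarray, learner_grid: dict | None = None,
             seed: int = 0, n_outer: int = 5, n_inner: int = 3) -> dict:
    """Nested-CV evaluation of a descriptor matrix on a QSAR task.

    Outer folds are random (shuffled K-fold) or the MACCS K-means clusters,
    by ``task.split_kind``; the inner grid search (RBF-kernel SVM) and the
    feature standardization are fitted on training folds only. Returns
    per-fold metrics (r^2 for regression, ROC AUC for classification) and
    their mean.
    """
    if X.shape[0] != len(task.molecules):
        raise ValueError("descriptor rows must align with task molecules")
    y = np.asarray(task.labels, dtype=np.float64)
    grid = learner_grid or _SVM_GRID
    if task.split_kind == "cluster_cv":
        labels = cluster_split(task.molecules, K=n_outer, seed=seed)
        folds = [(np.nonzero(labels != k)[0], np.nonzero(labels == k)[0])
                 for k in range(n_outer)]
    else:
        kf = KFold(n_splits=n_outer, shuffle=True, random_state=seed)
        folds = list(kf.split(X))
    per_fold = []
    for train, test in folds:
        if task.kind == "classification":
            if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                warnings.warn("fold with a single class skipped")
                continue
            model = SVC(kernel="rbf")
        else:
            model = SVR(kernel="rbf")
        pipe = Pipeline([("scale", StandardScaler()), ("model", model)])
        search = GridSearchCV(pipe, grid, cv=n_inner,
                              scoring=("roc_auc" if task.kind == "classification"
                                       else "r2"))
        search.fit(X[train], y[train])
        if task.kind == "classification":
            score = search.decision_function(X[test])
            metric = roc_auc(score[y[test] == 1], score[y[test] == 0])
        else:
            pred = search.predict(X[test])
            ss_res = float(((y[test] - pred) ** 2).sum())
            ss_tot = float(((y[test] - y[test].mean()) ** 2).sum())
            metric = 1.0 - ss_res / ss_tot
        per_fold.append(metric)
    if not per_fold:
        raise ValueError("no usable folds")
    return {"per_fold": per_fold, "mean": float(np.mean(per_fold)),
            "metric": "roc_auc" if task.kind == "classification" else "r2"}


def vs_screen(active_X: np.ndarray, decoy_X: np.ndarray,
              similarity: str = "cosine", seed: int = 0, n_queries: int = 5,
              n_reps: int = 50, fusion: str = "max") -> float:
    """Mean ROC AUC of the group-fusion similarity screen.

    Per repetition: ``n_queries`` actives are drawn without replacement as
    queries; every remaining compound is scored by the max (or mean)
    similarity to the queries; ROC AUC uses the remaining actives as
    positives. Continuous descriptors are standardized jointly over
    actives + decoys before cosine similarity.
    """
    if active_X.shape[0] < n_queries + 1:
        raise ValueError(f"need more than {n_queries} actives")
    if similarity == "cosine":
        all_X = standardize_columns(np.vstack([active_X, decoy_X]))
        active_X = all_X[: active_X.shape[0]]
        decoy_X = all_X[active_X.shape[0]:]
        norms_a = np.linalg.norm(active_X, axis=1)
        norms_d = np.linalg.norm(decoy_X, axis=1)

        def sim_matrix(queries):
            qn = np.linalg.norm(queries, axis=1)
            sa = active_X @ queries.T / np.outer(np.maximum(norms_a, 1e-12),
                                                 np.maximum(qn, 1e-12))
            sd = decoy_X @ queries.T / np.outer(np.maximum(norms_d, 1e-12),
                                                np.maximum(qn, 1e-12))
            return sa, sd
    elif similarity == "tanimoto":
        def sim_matrix(queries):
            sa = np.array([[tanimoto_counts(x, q) for q in queries]
                           for x in active_X])
            sd = np.array([[tanimoto_counts(x, q) for q in queries]
                           for x in decoy_X])
            return sa, sd
    else:
        raise ValueError(f"unknown similarity {similarity!r}")
    fuse = {"max": np.max, "mean": np.mean}[fusion]
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(n_reps):
        q_idx = rng.choice(active_X.shape[0], size=n_queries, replace=False)
        rest = np.setdiff1d(np.arange(active_X.shape[0]), q_idx)
        sa, sd = sim_matrix(active_X[q_idx])
        pos = fuse(sa[rest], axis=1)
        neg = fuse(sd, axis=1)
        aucs.append(roc_auc(pos, neg))
    return float(np.mean(aucs))


def screen_target(target: VsTarget, descriptor_fn, similarity: str = "cosine",
                  seed: int = 0, fusion: str = "max") -> float:
    """Convenience wrapper: featurize a VsTarget's records and screen it."""
    a = featurize(target.actives, descriptor_fn)
    d = featurize(target.decoys, descriptor_fn)
    return vs_screen(a, d, similarity=similarity, seed=seed,
                     n_queries=target.n_queries, n_reps=target.n_reps,
                     fusion=fusion)


def compare_descriptors(results: dict[str, np.ndarray]) -> dict[tuple, float]:
    """Two-sided Wilcoxon signed-rank p for every descriptor pair.

    ``results`` maps a descriptor name to its per-target mean-AUC vector;
    vectors must be paired by target. All-zero differences give p = 1 with a
    warning (the test statistic is undefined there).
    """
    names = sorted(results)
    out: dict[tuple, float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = np.asarray(results[a]), np.asarray(results[b])
            if len(va) != len(vb) or len(va) < 6:
                raise ValueError("paired AUC vectors of length >= 6 required")
            diff = va - vb
            if np.all(diff == 0):
                warnings.warn(f"all differences zero for ({a}, {b}); p = 1")
                out[(a, b)] = 1.0
                continue
            out[(a, b)] = float(stats.wilcoxon(va, vb,
                                               alternative="two-sided").pvalue)
    return out
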