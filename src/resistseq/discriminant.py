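"""DAPC on the genotype matrix and snpzip-style structural-SNP selection.

Discriminant Analysis of Principal Components: center-and-scale the
dosage matrix, project onto the leading principal components, fit a
linear discriminant on the retained PCs (two phenotype classes give one
discriminant axis), and back-project the axis through the PC rotation to
obtain per-SNP loadings.  The number of retained PCs is chosen by
repeated stratified cross-validation on held-out assignment success.
The snpzip step splits the absolute loadings into two groups by Ward
clustering and returns the high-loading ("structural") group.
"""

from __future__ import annotations

from dataclasses import dataclass

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

MAX_MISSING = 0.05


@dataclass
class PruneReport:
    n_input: int
    n_monomorphic: int
    n_high_missing: int
    n_kept: int
    imputed_fraction: float


def prune_snps(X: pd.DataFrame, max_missing: float = MAX_MISSING
               ) -> tuple[pd.DataFrame, PruneReport]:
    """Drop cohort-monomorphic SNPs and SNPs with > 5% missing calls.

    ``X`` is samples x SNPs dosage with NaN for missing.  Monomorphic
    means a single observed dosage value across the cohort — including
    SNPs fixed for the alternate allele (different from the reference but
    invariant here).  Remaining missing entries are mean-imputed so the
    decomposition has a complete matrix; the imputed fraction is recorded.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    missing_frac = X.isna().mean(axis=0)
    nunique = X.nunique(axis=0, dropna=True)
    mono = nunique <= 1
    high_missing = missing_frac > max_missing
    keep = ~(mono | high_missing)
    if not keep.any():
        raise ValueError("no SNPs left after pruning")
    pruned = X.loc[:, keep].copy()
    n_imputed = int(pruned.isna().to_numpy().sum())
    pruned = pruned.fillna(pruned.mean(axis=0))
    return pruned, PruneReport(
        n_input=X.shape[1],
        n_monomorphic=int((mono & ~high_missing).sum()),
        n_high_missing=int(high_missing.sum()),
        n_kept=int(keep.sum()),
        imputed_fraction=n_imputed / pruned.size if pruned.size else 0.0,
    )


class DAPC(BaseEstimator, ClassifierMixin):
    """Two-group DAPC with per-SNP loadings.

    Parameters
    ----------
    n_pcs : number of principal components retained before the
        discriminant step (choose with :func:`xval_retain`).

    Fitted attributes: ``loadings_`` (per-SNP weights of the single
    discriminant axis, back-projected through the PC rotation on the
    standardized dosage scale), ``scores_`` (per-sample discriminant
    coordinates), ``reassignment_rate_`` (training samples assigned back
    to their own group), ``classes_``.
    """

    def __init__(self, n_pcs: int = 1):
        self.n_pcs = n_pcs

    def fit(self, X, y) -> "DAPC":
        X = pd.DataFrame(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("DAPC here supports exactly two groups")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        if self.n_pcs >= X.shape[0]:
            raise ValueError("n_pcs must be below the number of samples")
        self._scaler = StandardScaler()
        z = self._scaler.fit_transform(X.to_numpy(dtype=float))
        self._pca = PCA(n_components=self.n_pcs, svd_solver="full")
        pcs = self._pca.fit_transform(z)
        self._lda = LinearDiscriminantAnalysis()
        self._lda.fit(pcs, y)
        self.classes_ = self._lda.classes_
        coef = self._lda.coef_[0]  # one axis for two classes
        self.loadings_ = pd.Series(self._pca.components_.T @ coef,
                                   index=X.columns, name="loading")
        self.scores_ = pd.Series(self._lda.decision_function(pcs),
                                 index=X.index, name="score")
        self.reassignment_rate_ = float((self._lda.predict(pcs) == y).mean())
        return self

    def predict(self, X):
        z = self._scaler.transform(pd.DataFrame(X).to_numpy(dtype=float))
        return self._lda.predict(self._pca.transform(z))

    def score(self, X, y, sample_weight=None) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())


def dapc_fit(X: pd.DataFrame, y: Sequence[str], n_pcs: int = 1) -> DAPC:
    """Functional wrapper over :class:`DAPC`."""
    return DAPC(n_pcs=n_pcs).fit(X, y)


def xval_retain(X: pd.DataFrame, y: Sequence[str],
                candidates: Sequence[int] = (1, 2, 5, 10, 20),
                folds: int = 5, reps: int = 5,
                seed: int | None = 0) -> tuple[int, pd.Series]:
    """Choose the retained-PC count by repeated stratified cross-validation.

    For each candidate, mean held-out assignment success over
    ``reps`` x ``folds`` stratified splits; ties go to the fewest PCs.
    Returns (best n_pcs, mean score per candidate).
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    _, class_counts = np.unique(y, return_counts=True)
    if class_counts.min() < folds:
        raise ValueError("each class needs at least `folds` members")
    candidates = sorted({int(c) for c in candidates})
    max_train = X.shape[0] - int(np.ceil(X.shape[0] / folds))
    candidates = [c for c in candidates if 1 <= c < max_train]
    if not candidates:
        raise ValueError("no feasible candidate PC counts")
    rng = np.random.default_rng(seed)
    scores = {c: [] for c in candidates}
    max_pcs = max(candidates)
    for _ in range(reps):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        for train, test in skf.split(X, y):
            # PCA components are nested, so one decomposition per split
            # serves every candidate
            scaler = StandardScaler().fit(X.iloc[train])
            pca = PCA(n_components=max_pcs, svd_solver="full").fit(
                scaler.transform(X.iloc[train]))
            pcs_train = pca.transform(scaler.transform(X.iloc[train]))
            pcs_test = pca.transform(scaler.transform(X.iloc[test]))
            for c in candidates:
                lda = LinearDiscriminantAnalysis().fit(pcs_train[:, :c],
                                                       y[train])
                scores[c].append(
                    float((lda.predict(pcs_test[:, :c]) == y[test]).mean()))
    mean_scores = pd.Series({c: float(np.mean(v)) for c, v in scores.items()})
    best = int(mean_scores.index[np.argmax(mean_scores.to_numpy())])
    # argmax takes the first (smallest) candidate on exact ties
    return best, mean_scores


def snpzip_select(loadings: pd.Series) -> tuple[list, bool]:
    """Split SNPs into structural vs background by their |loading|.

    Ward 2-group clustering of the absolute loadings; the cluster with
    the larger mean |loading| is returned, ordered by descending
    |loading|.  All-equal loadings are unsplittable: empty list, flagged.
    """
    loadings = pd.Series(loadings)
    if len(loadings) < 2:
        raise ValueError("need at least two SNPs")
    mag = loadings.abs()
    if np.allclose(mag.to_numpy(), mag.to_numpy()[0]):
        return [], True
    # order-invariant clustering: cluster the sorted magnitudes
    order = mag.sort_values(kind="stable").index
    z = linkage(mag.loc[order].to_numpy()[:, None], method="ward")
    groups = fcluster(z, t=2, criterion="maxclust")
    labels = pd.Series(groups, index=order)
    means = mag.groupby(labels).mean()
    structural = labels.index[labels == means.idxmax()]
    return list(mag.loc[structural].sort_values(ascending=False).index), False


@dataclass
class SnpzipResult:
    n_pcs_retained: int
    xval_scores: pd.Series
    loadings: pd.Series
    scores: pd.Series
    reassignment_rate: float
    structural_snps: list
    prune_report: PruneReport
    degenerate: bool


def snpzip(X: pd.DataFrame, y: Sequence[str],
           max_missing: float = MAX_MISSING,
           n_pcs: int | None = None,
           candidates: Sequence[int] = (1, 2, 5, 10, 20),
           folds: int = 5, reps: int = 5,
           seed: int | None = 0) -> SnpzipResult:
    """Prune -> (xval) -> DAPC -> structural-SNP selection, end to end."""
    pruned, report = prune_snps(X, max_missing=max_missing)
    if n_pcs is None:
        n_pcs, xval_scores = xval_retain(pruned, y, candidates=candidates,
                                         folds=folds, reps=reps, seed=seed)
    else:
        xval_scores = pd.Series(dtype=float)
    model = DAPC(n_pcs=n_pcs).fit(pruned, y)
    selected, degenerate = snpzip_select(model.loadings_)
    return SnpzipResult(n_pcs_retained=n_pcs, xval_scores=xval_scores,
                        loadings=model.loadings_, scores=model.scores_,
                        reassignment_rate=model.reassignment_rate_,
                        structural_snps=selected, prune_report=report,
                        degenerate=degenerate)
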