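"""Read-depth CNV detection and qPCR fold-change validation math.

The depth cascade follows the CoNIFER design for targeted panels:
per-amplicon RPKM (reads per kilobase per million mapped), per-amplicon
z-scores across samples (ZRPKM), then SVD denoising that zeroes the k
largest singular components to strip batch structure (SVD-ZRPKM).  Genes
are then compared between phenotype groups: a fold change of gene-level
mean RPKM (resistant / susceptible), a Welch t-test on gene-level
SVD-ZRPKM signals, an mRMR ranking of gene signals against the phenotype,
and a total duplicated/deleted determination per gene (duplicated iff the
resistant group mean exceeds the susceptible group mean).

qPCR validation uses the comparative-Cq method: ddCq relative to a
single-copy reference gene and a susceptible control sample, fold change
2^(-ddCq), with >= 1.5 taken as support for increased copy number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import DepthMatrix

FOLD_THRESHOLD = 1.5
T_ALPHA = 0.05
DEFAULT_SVD_K = 2


def rpkm(counts: np.ndarray | pd.DataFrame,
         amplicon_lengths: Sequence[float] | np.ndarray,
         totals: Sequence[float] | np.ndarray | None = None):
    """RPKM layer: reads / (length_kb x total_mapped_millions).

    ``counts`` is amplicons x samples; ``totals`` defaults to the
    per-sample column sums.
    """
    values = np.asarray(counts, dtype=float)
    lengths = np.asarray(amplicon_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("amplicon lengths must be positive")
    if totals is None:
        totals = values.sum(axis=0)
    totals = np.asarray(totals, dtype=float)
    if (totals <= 0).any():
        raise ValueError("per-sample totals must be positive")
    out = values / (lengths[:, None] / 1e3) / (totals[None, :] / 1e6)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def zrpkm(rpkm_layer: np.ndarray | pd.DataFrame):
    """Per-amplicon standardization across samples.

    Returns (z, keep) where ``keep`` flags amplicons with non-zero
    variance; zero-variance amplicons are dropped from the z layer (and
    therefore from the SVD).
    """
    values = np.asarray(rpkm_layer, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need at least two samples to standardize")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    keep = sd[:, 0] > 0
    z = (values[keep] - mean[keep]) / sd[keep]
    if isinstance(rpkm_layer, pd.DataFrame):
        keep = pd.Series(keep, index=rpkm_layer.index)
        z = pd.DataFrame(z, index=rpkm_layer.index[keep.to_numpy()],
                         columns=rpkm_layer.columns)
    return z, keep


def svd_denoise(z: np.ndarray | pd.DataFrame, k: int):
    """Reconstruct the z matrix with the k largest singular components
    zeroed; k = 0 is the identity."""
    values = np.asarray(z, dtype=float)
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= min(values.shape):
        raise ValueError(f"k={k} must be below min(shape)={min(values.shape)}")
    if k == 0:
        out = values.copy()
    else:
        u, s, vt = np.linalg.svd(values, full_matrices=False)
        s = s.copy()
        s[:k] = 0.0
        out = (u * s) @ vt
    if isinstance(z, pd.DataFrame):
        return pd.DataFrame(out, index=z.index, columns=z.columns)
    return out


def gene_signals(layer: pd.DataFrame, gene_ids: pd.Series) -> pd.DataFrame:
    """Genes x samples matrix of per-sample means over each gene's amplicons."""
    genes = gene_ids.reindex(layer.index)
    return layer.groupby(genes).mean()


# ---------------------------------------------------------------------------
# mRMR

def _tercile_bins(x: np.ndarray) -> np.ndarray:
    lo, hi = np.quantile(x, [1 / 3, 2 / 3])
    return np.digitize(x, [lo, hi])


def _mi_discrete(a: np.ndarray, b: np.ndarray, ka: int = 3, kb: int = 3
                 ) -> float:
    """Mutual information (nats) of two small-alphabet discrete vectors."""
    joint = np.bincount(ka * b + a, minlength=ka * kb).reshape(kb, ka)
    joint = joint / joint.sum()
    pa = joint.sum(axis=0)
    pb = joint.sum(axis=1)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz]
                                           / np.outer(pb, pa)[nz])))


def mrmr_rank(features: pd.DataFrame, target: Sequence) -> pd.Series:
    """Greedy minimum-redundancy maximum-relevance ranking (MID variant).

    ``features`` is samples x features (gene signals); ``target`` the
    phenotype labels.  Mutual information is computed on
    tercile-discretized signals.  The first pick maximizes relevance
    MI(f, y); each later pick maximizes relevance minus mean redundancy
    with the already-selected set.  Zero-relevance (e.g. constant)
    features are appended last in input order.  Deterministic; returns a
    Series of ranks (1 = selected first) indexed like the columns.
    """
    if features.shape[1] < 2:
        raise ValueError("mRMR needs at least two features")
    y = pd.factorize(np.asarray(target))[0]
    n_classes = int(y.max()) + 1
    cols = list(features.columns)
    disc = {c: _tercile_bins(features[c].to_numpy(dtype=float)) for c in cols}
    relevance = {c: _mi_discrete(disc[c], y, 3, n_classes) for c in cols}

    active = [c for c in cols if relevance[c] > 0]
    inert = [c for c in cols if relevance[c] <= 0]
    selected: list = []
    mi_cache: dict[tuple, float] = {}

    def redundancy(c) -> float:
        if not selected:
            return 0.0
        total = 0.0
        for s in selected:
            key = (c, s)
            if key not in mi_cache:
                mi_cache[key] = _mi_discrete(disc[c], disc[s])
            total += mi_cache[key]
        return total / len(selected)

    remaining = list(active)
    while remaining:
        scores = [(relevance[c] - redundancy(c), -remaining.index(c), c)
                  for c in remaining]
        best = max(scores)[2]
        selected.append(best)
        remaining.remove(best)
    order = selected + inert
    return pd.Series({c: i + 1 for i, c in enumerate(order)},
                     name="mrmr_rank").reindex(cols)


# ---------------------------------------------------------------------------
# group-level determination

def group_cnv_stats(svd_signals: pd.DataFrame, rpkm_signals: pd.DataFrame,
                    labels: Sequence[str]) -> pd.DataFrame:
    """Per-gene CNV statistics between phenotype groups.

    ``svd_signals``/``rpkm_signals`` are genes x samples gene-level
    matrices; ``labels`` the resistant/susceptible phenotype per sample.
    Every gene receives exactly one determination: duplicated iff the
    resistant group mean SVD-ZRPKM signal exceeds (or ties, flagged) the
    susceptible one, else deleted.  fold_change is the ratio of gene-level
    mean RPKM (resistant / susceptible).
    """
    labels = np.asarray(labels)
    res = labels == "resistant"
    sus = labels == "susceptible"
    if res.sum() < 2 or sus.sum() < 2:
        raise ValueError("each phenotype group needs >= 2 samples")
    rows = []
    for gene_id in svd_signals.index:
        sig = svd_signals.loc[gene_id].to_numpy(dtype=float)
        mean_res, mean_sus = sig[res].mean(), sig[sus].mean()
        t_stat, t_p = stats.ttest_ind(sig[res], sig[sus], equal_var=False)
        rp = rpkm_signals.loc[gene_id].to_numpy(dtype=float)
        sus_mean_rpkm = rp[sus].mean()
        fold = rp[res].mean() / sus_mean_rpkm if sus_mean_rpkm > 0 else np.nan
        rows.append({
            "gene_id": gene_id,
            "fold_change": fold,
            "mean_signal_resistant": mean_res,
            "mean_signal_susceptible": mean_sus,
            "t_stat": float(t_stat), "t_p": float(t_p),
            "determination": ("duplicated" if mean_res >= mean_sus
                              else "deleted"),
            "tie": bool(mean_res == mean_sus),
        })
    out = pd.DataFrame(rows).set_index("gene_id")
    ranks = mrmr_rank(svd_signals.T, labels)
    out["mrmr_rank"] = ranks
    return out


class ConiferCnv(BaseEstimator):
    """Sklearn-style CNV analyzer for an amplicon depth matrix.

    Parameters
    ----------
    svd_k : number of leading singular components removed (default 2 for
        panel-scale cohorts; a scree report of singular values is stored
        in ``singular_values_`` to guide the choice).
    t_alpha : Welch t-test significance threshold used by
        ``significant_duplications()``.

    ``fit(X, y, amplicons=...)`` takes samples x amplicons counts, labels,
    and amplicon metadata (gene_id, length).  Fitted layers: ``rpkm_``,
    ``zrpkm_``, ``svd_zrpkm_`` (amplicons x samples) and the per-gene
    ``gene_results_`` table.
    """

    def __init__(self, svd_k: int = DEFAULT_SVD_K, t_alpha: float = T_ALPHA):
        self.svd_k = svd_k
        self.t_alpha = t_alpha

    def fit(self, X: pd.DataFrame, y: Sequence[str], *,
            amplicons: pd.DataFrame) -> "ConiferCnv":
        counts = X.T  # amplicons x samples
        lengths = amplicons["length"].reindex(counts.index)
        if lengths.isna().any():
            raise ValueError("amplicon metadata does not cover all counts")
        self.rpkm_ = rpkm(counts, lengths.to_numpy())
        self.zrpkm_, self.kept_amplicons_ = zrpkm(self.rpkm_)
        self.singular_values_ = np.linalg.svd(
            self.zrpkm_.to_numpy(), compute_uv=False)
        self.svd_zrpkm_ = svd_denoise(self.zrpkm_, self.svd_k)
        gene_ids = amplicons["gene_id"]
        svd_sig = gene_signals(self.svd_zrpkm_, gene_ids)
        rpkm_sig = gene_signals(self.rpkm_, gene_ids)
        skipped = set(gene_ids.unique()) - set(svd_sig.index)
        if skipped:
            import warnings
            warnings.warn(f"genes without usable amplicons skipped: "
                          f"{sorted(skipped)}")
        self.gene_results_ = group_cnv_stats(svd_sig, rpkm_sig, np.asarray(y))
        return self

    def significant_duplications(self) -> pd.DataFrame:
        """Genes determined duplicated with t_p <= t_alpha (the reported
        'present in greater copy numbers in resistant' list)."""
        g = self.gene_results_
        return g[(g["determination"] == "duplicated")
                 & (g["t_p"] <= self.t_alpha)].sort_values("t_p")


def analyze_depths(depths: DepthMatrix, phenotypes: pd.DataFrame,
                   insecticide: str, svd_k: int = DEFAULT_SVD_K,
                   t_alpha: float = T_ALPHA) -> ConiferCnv:
    """Run the CNV stage on a depth matrix against one insecticide."""
    common = [s for s in depths.samples if s in phenotypes.index]
    labels = phenotypes.loc[common, insecticide].to_numpy()
    est = ConiferCnv(svd_k=svd_k, t_alpha=t_alpha)
    return est.fit(depths.counts[common].T, labels, amplicons=depths.amplicons)


# ---------------------------------------------------------------------------
# qPCR validation math

@dataclass
class QpcrResult:
    """Comparative-Cq fold change for one (sample, gene)."""

    sample: str
    gene: str
    mean_cq_target: float
    mean_cq_reference: float
    ddcq: float
    fold_change: float
    amplified: bool


def qpcr_fold_change(sample_target_cq: Sequence[float],
                     sample_reference_cq: Sequence[float],
                     control_target_cq: Sequence[float],
                     control_reference_cq: Sequence[float],
                     sample: str = "sample", gene: str = "gene",
                     threshold: float = FOLD_THRESHOLD) -> QpcrResult:
    """ddCq fold change on (triplicate) well means.

    ddCq = (Cq_target - Cq_reference)_sample - (Cq_target - Cq_reference)_control,
    fold = 2^(-ddCq); ``amplified`` iff fold >= threshold (inclusive).
    """
    means = []
    for name, wells in (("sample target", sample_target_cq),
                        ("sample reference", sample_reference_cq),
                        ("control target", control_target_cq),
                        ("control reference", control_reference_cq)):
        wells = np.asarray(wells, dtype=float)
        if wells.size == 0:
            raise ValueError(f"missing {name} wells")
        if (wells <= 0).any():
            raise ValueError(f"{name} Cq values must be positive")
        means.append(float(wells.mean()))
    mt, mr, ct, cr = means
    ddcq = (mt - mr) - (ct - cr)
    fold = float(2.0 ** (-ddcq))
    return QpcrResult(sample=sample, gene=gene, mean_cq_target=mt,
                      mean_cq_reference=mr, ddcq=float(ddcq),
                      fold_change=fold, amplified=fold >= threshold)


def qpcr_table(cq: pd.DataFrame, control_sample: str,
               threshold: float = FOLD_THRESHOLD) -> pd.DataFrame:
    """Fold changes for every (sample, gene) in a long Cq table.

    ``cq`` columns: sample, gene, role in {target, reference}, replicate,
    cq.  The control sample must have target and reference wells for each
    gene assayed.
    """
    rows = []
    for gene, sub in cq.groupby("gene", sort=False):
        ctrl = sub[sub["sample"] == control_sample]
        ct = ctrl.loc[ctrl["role"] == "target", "cq"].to_numpy()
        cr = ctrl.loc[ctrl["role"] == "reference", "cq"].to_numpy()
        for sample, ss in sub[sub["sample"] != control_sample].groupby(
                "sample", sort=False):
            st = ss.loc[ss["role"] == "target", "cq"].to_numpy()
            sr = ss.loc[ss["role"] == "reference", "cq"].to_numpy()
            res = qpcr_fold_change(st, sr, ct, cr, sample=sample, gene=gene,
                                   threshold=threshold)
            rows.append(vars(res))
    return pd.DataFrame(rows)
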