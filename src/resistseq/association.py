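"""Per-SNP association statistics and the Data Set 1 -> 2 -> 3 cascade.

For each SNP and insecticide the pipeline computes:

* a two-sided Fisher exact test on the carrier-coded 2x2 table
  (phenotype x carrier status, carrier = at least one alternate allele);
* sensitivity  = resistant carriers / resistant samples,
  specificity  = susceptible reference-only / susceptible samples,
  AUC          = (sensitivity + specificity) / 2 — the study's
  informativeness metric, not a ROC integral;
* the Cochran-Armitage trend test (CATT) on the full 3x2 genotype table
  with co-dominant scores (0, 1, 2), chi-squared with 1 df.

Data Set 1 is every QC-passing SNP; Data Set 2 keeps in-gene (exonic)
SNPs with Fisher p <= 0.10 sorted by descending AUC; Data Set 3 keeps
the Data Set 2 SNPs with CATT p <= 0.05.  Thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import GenotypeMatrix, validate_phenotypes

FISHER_ALPHA = 0.10
CATT_ALPHA = 0.05


@dataclass
class CarrierTable:
    """2x2 carrier table: rows phenotype (resistant, susceptible), columns
    carrier status (>= 1 alternate allele, reference-only)."""

    res_carrier: int
    res_ref: int
    sus_carrier: int
    sus_ref: int
    n_missing: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([[self.res_carrier, self.res_ref],
                         [self.sus_carrier, self.sus_ref]])

    @property
    def n_resistant(self) -> int:
        return self.res_carrier + self.res_ref

    @property
    def n_susceptible(self) -> int:
        return self.sus_carrier + self.sus_ref


def carrier_table(dosages: Sequence[float] | np.ndarray,
                  labels: Sequence[str] | np.ndarray) -> CarrierTable:
    """Collapse dosages to carrier status against binary phenotype labels.

    Individuals with a missing dosage are excluded (complete-case per
    site) and counted in ``n_missing``.
    """
    dosages = np.asarray(dosages, dtype=float)
    labels = np.asarray(labels)
    if dosages.shape != labels.shape:
        raise ValueError("dosages and labels must align")
    keep = ~np.isnan(dosages)
    n_missing = int((~keep).sum())
    if not keep.any():
        raise ValueError("all individuals missing at this site")
    dosages, labels = dosages[keep], labels[keep]
    carrier = dosages >= 1
    res = labels == "resistant"
    return CarrierTable(
        res_carrier=int((res & carrier).sum()),
        res_ref=int((res & ~carrier).sum()),
        sus_carrier=int((~res & carrier).sum()),
        sus_ref=int((~res & ~carrier).sum()),
        n_missing=n_missing,
    )


def fisher_exact(table: CarrierTable | np.ndarray) -> tuple[float, bool]:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities of
    tables as or less probable than the observed one, margins fixed).

    A zero margin carries no information: returns (1.0, flagged=True).
    """
    arr = table.as_array() if isinstance(table, CarrierTable) else np.asarray(table)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0, True
    return float(stats.fisher_exact(arr, alternative="two-sided")[1]), False


def sens_spec_auc(table: CarrierTable) -> tuple[float, float, float]:
    """Carrier-based sensitivity/specificity and their average (the AUC)."""
    if table.n_resistant == 0 or table.n_susceptible == 0:
        raise ValueError("both phenotype groups must be non-empty")
    sens = table.res_carrier / table.n_resistant
    spec = table.sus_ref / table.n_susceptible
    return sens, spec, (sens + spec) / 2.0


def genotype_counts(dosages: Sequence[float] | np.ndarray,
                    labels: Sequence[str] | np.ndarray) -> np.ndarray:
    """3x2 table of dosage (0/1/2) by phenotype (resistant, susceptible)."""
    dosages = np.asarray(dosages, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(dosages)
    dosages, labels = dosages[keep], labels[keep]
    out = np.zeros((3, 2), dtype=int)
    for d in (0, 1, 2):
        sel = dosages == d
        out[d, 0] = int((sel & (labels == "resistant")).sum())
        out[d, 1] = int((sel & (labels == "susceptible")).sum())
    return out


def catt(counts: np.ndarray,
         scores: Sequence[float] = (0.0, 1.0, 2.0)) -> tuple[float, float, bool]:
    """Cochran-Armitage trend test on a genotype-by-phenotype table.

    ``counts`` is k x 2 (genotype category x phenotype, resistant first);
    ``scores`` are the co-dominant dosage scores.  The statistic is the
    squared score-test Z for a linear trend in the resistant proportion,
    referred to chi-squared with 1 df.  A monomorphic table (all samples
    in one genotype row) carries no trend information: (0.0, 1.0, True).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 2 or (counts < 0).any():
        raise ValueError("need a non-negative k x 2 table")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("both phenotype columns must be non-empty")
    w = np.asarray(scores, dtype=float)
    if w.shape != (counts.shape[0],):
        raise ValueError("scores must match the number of genotype rows")
    n_i = counts.sum(axis=1)
    if (n_i > 0).sum() < 2:
        return 0.0, 1.0, True
    n = counts.sum()
    r = counts[:, 0].sum()          # resistant (case) total
    pbar = r / n
    t = float(np.sum(w * (counts[:, 0] - n_i * pbar)))
    var = pbar * (1 - pbar) * (np.sum(w**2 * n_i) - np.sum(w * n_i) ** 2 / n)
    if var <= 0:
        return 0.0, 1.0, True
    stat = t * t / var
    return float(stat), float(stats.chi2.sf(stat, df=1)), False


# ---------------------------------------------------------------------------
# cohort-level table

def associate(genotypes: GenotypeMatrix, phenotypes: pd.DataFrame,
              insecticide: str,
              annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-SNP association table (Data Set 1 augmented with statistics).

    Returns one row per site with the carrier-table counts, Fisher p,
    sensitivity/specificity/AUC, CATT statistic and p, and — when an
    annotation table is supplied — the reporting gene/region/effect of
    each site.  A Benjamini-Hochberg column on the Fisher p-values is
    emitted for information only; the cascade uses raw thresholds.
    """
    validate_phenotypes(phenotypes, insecticide)
    common = [s for s in genotypes.samples if s in phenotypes.index]
    if not common:
        raise ValueError("no samples shared between genotypes and phenotypes")
    labels = phenotypes.loc[common, insecticide].to_numpy()
    dosage = genotypes.dosage[common]
    rows = []
    for site_id in genotypes.sites.index:
        d = dosage.loc[site_id].to_numpy(dtype=float)
        table = carrier_table(d, labels)
        fisher_p, fisher_flag = fisher_exact(table)
        sens, spec, auc = sens_spec_auc(table)
        counts = genotype_counts(d, labels)
        catt_stat, catt_p, catt_flag = catt(counts)
        rows.append({
            "site_id": site_id,
            "supercontig": genotypes.sites.at[site_id, "supercontig"],
            "position": genotypes.sites.at[site_id, "position"],
            "insecticide": insecticide,
            "n_missing": table.n_missing,
            "res_carrier": table.res_carrier, "res_ref": table.res_ref,
            "sus_carrier": table.sus_carrier, "sus_ref": table.sus_ref,
            "fisher_p": fisher_p, "fisher_flag": fisher_flag,
            "sensitivity": sens, "specificity": spec, "auc": auc,
            "catt_stat": catt_stat, "catt_p": catt_p, "catt_flag": catt_flag,
        })
    result = pd.DataFrame(rows).set_index("site_id")
    result["fisher_p_bh"] = multipletests(result["fisher_p"],
                                          method="fdr_bh")[1]
    if annotations is not None:
        first = annotations.drop_duplicates("site_id").set_index("site_id")
        for col in ("gene_id", "region", "effect"):
            result[col] = first[col].reindex(result.index)
    return result


def build_dataset2(results: pd.DataFrame,
                   fisher_alpha: float = FISHER_ALPHA) -> pd.DataFrame:
    """In-gene (exonic) SNPs with Fisher p <= alpha, sorted by descending
    AUC; ties broken by genomic order (supercontig, position).  Flanking
    and intron SNPs are disregarded."""
    if "region" not in results.columns:
        raise ValueError("Data Set 2 needs annotated results (region column)")
    keep = (results["region"] == "exon") & (results["fisher_p"] <= fisher_alpha)
    ds2 = results[keep].copy()
    ds2 = ds2.sort_values(["supercontig", "position"]).sort_values(
        "auc", ascending=False, kind="stable")
    return ds2


def build_dataset3(dataset2: pd.DataFrame,
                   catt_alpha: float = CATT_ALPHA) -> pd.DataFrame:
    """The Data Set 2 subset with CATT p <= alpha, sorted by CATT p."""
    ds3 = dataset2[dataset2["catt_p"] <= catt_alpha].copy()
    return ds3.sort_values(["catt_p", "supercontig", "position"],
                           kind="stable")


def snps_per_gene(dataset: pd.DataFrame) -> pd.Series:
    """SNP counts per reporting gene, descending."""
    return (dataset.groupby("gene_id").size()
            .sort_values(ascending=False))


def shared_snp_summary(snp_sets: Mapping[str, Iterable[str]]
                       ) -> tuple[set[str], int, int]:
    """Intersection across comparisons, the total number of distinct SNPs,
    and the shared percentage (rounded to a whole percent, as reported)."""
    sets = [set(v) for v in snp_sets.values()]
    if not sets:
        return set(), 0, 0
    shared = set.intersection(*sets)
    total = len(set.union(*sets))
    pct = int(round(100.0 * len(shared) / total)) if total else 0
    return shared, total, pct


def population_frequencies(genotypes: GenotypeMatrix,
                           phenotypes: pd.DataFrame,
                           insecticide: str,
                           site_ids: Sequence[str] | None = None
                           ) -> pd.DataFrame:
    """Carrier frequencies per population and per phenotype group.

    One row per site: the carrier frequency (fraction of non-missing
    individuals with >= 1 alternate allele) in each population, among
    resistant and among susceptible individuals, and the
    resistant-minus-susceptible difference reported to two decimals.
    Empty populations are flagged as NaN.
    """
    validate_phenotypes(phenotypes, insecticide)
    if site_ids is None:
        site_ids = list(genotypes.sites.index)
    common = [s for s in genotypes.samples if s in phenotypes.index]
    pops = phenotypes.loc[common, "population"]
    labels = phenotypes.loc[common, insecticide]
    rows = []
    for site_id in site_ids:
        d = genotypes.dosage.loc[site_id, common]
        carrier = d >= 1
        ok = d.notna()
        row = {"site_id": site_id}
        # frequencies reported to two decimals, matching the published
        # per-population tables; the difference uses the reported values
        for pop in pd.unique(pops):
            sel = ok & (pops == pop).to_numpy()
            row[f"freq_{pop}"] = (round(float(carrier[sel].mean()), 2)
                                  if sel.any() else np.nan)
        for group, col in (("resistant", "freq_resistant"),
                           ("susceptible", "freq_susceptible")):
            sel = ok & (labels == group).to_numpy()
            row[col] = (round(float(carrier[sel].mean()), 2)
                        if sel.any() else np.nan)
        row["difference"] = round(row["freq_resistant"]
                                  - row["freq_susceptible"], 2)
        rows.append(row)
    return pd.DataFrame(rows).set_index("site_id")


# ---------------------------------------------------------------------------
# estimator facade

class SnpAssociation(BaseEstimator):
    """Sklearn-style facade over the association cascade.

    Parameters
    ----------
    insecticide : phenotype column to test against.
    fisher_alpha, catt_alpha : inclusive cascade thresholds
        (Fisher p <= 0.10 into Data Set 2, CATT p <= 0.05 into Data Set 3).

    ``fit(X, y)`` takes a samples-by-SNPs dosage DataFrame and labels;
    fitted attributes are ``results_`` (Data Set 1 with statistics),
    ``dataset2_`` and ``dataset3_``.
    """

    def __init__(self, insecticide: str = "permethrin",
                 fisher_alpha: float = FISHER_ALPHA,
                 catt_alpha: float = CATT_ALPHA):
        self.insecticide = insecticide
        self.fisher_alpha = fisher_alpha
        self.catt_alpha = catt_alpha

    def fit(self, X: pd.DataFrame, y: Sequence[str],
            annotations: pd.DataFrame | None = None,
            populations: Sequence[str] | None = None) -> "SnpAssociation":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples-by-SNPs dosage DataFrame")
        sites = _sites_from_columns(X.columns)
        genotypes = GenotypeMatrix(sites=sites, dosage=X.T)
        pheno = pd.DataFrame(index=X.index)
        pheno["population"] = (list(populations) if populations is not None
                               else "all")
        pheno[self.insecticide] = np.asarray(y)
        self.results_ = associate(genotypes, pheno, self.insecticide,
                                  annotations)
        if annotations is not None:
            self.dataset2_ = build_dataset2(self.results_, self.fisher_alpha)
            self.dataset3_ = build_dataset3(self.dataset2_, self.catt_alpha)
        return self


def _sites_from_columns(columns: Iterable[str]) -> pd.DataFrame:
    rows = []
    for i, col in enumerate(columns):
        if ":" in str(col):
            sc, pos = str(col).rsplit(":", 1)
            rows.append({"site_id": col, "supercontig": sc,
                         "position": int(pos), "ref": "N", "alt": "N"})
        else:
            rows.append({"site_id": col, "supercontig": "unknown",
                         "position": i + 1, "ref": "N", "alt": "N"})
    return pd.DataFrame(rows).set_index("site_id")
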