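"""In-memory containers shared across pipeline stages.

Genotypes are stored as alternate-allele dosage (0/1/2, NaN for missing)
per site per individual; read depths as integer counts per amplicon per
sample.  Both wrap pandas DataFrames, which remain directly accessible.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

PHENOTYPES = ("resistant", "susceptible")


@dataclass
class GenotypeMatrix:
    """Per-site dosage matrix plus site metadata.

    ``sites``: DataFrame indexed by ``site_id`` ("supercontig:position")
    with columns supercontig, position, ref, alt (comma-joined alts).
    ``dosage``: DataFrame indexed by ``site_id``, one column per sample,
    float values in {0, 1, 2} with NaN for missing calls.
    """

    sites: pd.DataFrame
    dosage: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.sites.index.equals(self.dosage.index):
            raise ValueError("sites and dosage indexes disagree")
        valid = self.dosage.isna() | self.dosage.isin([0.0, 1.0, 2.0])
        if not valid.to_numpy().all():
            raise ValueError("dosage values must be 0/1/2 or missing")

    @property
    def samples(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def samples_by_sites(self) -> pd.DataFrame:
        """Samples-as-rows orientation used by the sklearn-style estimators."""
        return self.dosage.T


@dataclass
class DepthMatrix:
    """Per-amplicon read counts plus amplicon metadata.

    ``amplicons``: DataFrame indexed by amplicon id with columns
    supercontig, start, end (0-based half-open, BED convention), gene_id,
    length, pool.  ``counts``: DataFrame indexed the same way, one column
    per sample, non-negative integers.
    """

    amplicons: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.amplicons.index.equals(self.counts.index):
            raise ValueError("amplicons and counts indexes disagree")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        if (self.amplicons["length"] <= 0).any():
            raise ValueError("amplicon lengths must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def validate_phenotypes(phenotypes: pd.DataFrame,
                        insecticide: str | None = None) -> None:
    """Check the phenotype table schema (index sample; population column;
    one column per insecticide with resistant/susceptible labels)."""
    if "population" not in phenotypes.columns:
        raise ValueError("phenotype table lacks a 'population' column")
    cols = [insecticide] if insecticide else [
        c for c in phenotypes.columns if c != "population"]
    for col in cols:
        if col not in phenotypes.columns:
            raise KeyError(f"no phenotype column {col!r}")
        bad = set(phenotypes[col].dropna()) - set(PHENOTYPES)
        if bad:
            raise ValueError(f"phenotype column {col!r} has labels {bad}")
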