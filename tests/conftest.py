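"""Shared fixtures: small gene panels and synthetic cohorts.

All fixture data is generated programmatically; the kdr-style gene is a
synthetic stand-in built so that codon 406 of its coding sequence is TTA
inside its sixth exon, mirroring the canonical L1014F locus layout.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from resistseq.gene_model import GeneModel, GenePanel
from resistseq.synthetic_data import (CausalSnpSpec, DuplicationSpec,
                                      PopulationSpec, SimulationConfig,
                                      simulate_cohort)

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

_CODONS_NO_STOP = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                   if a + b + c not in ("TAA", "TAG", "TGA")]


def random_codons(rng: np.random.Generator, n_codons: int) -> list[str]:
    """Random codon list without stop codons."""
    return list(rng.choice(_CODONS_NO_STOP, size=n_codons))


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random coding sequence without internal stop codons."""
    return "".join(random_codons(rng, n_codons))


def make_gene(gene_id: str, supercontig: str, strand: str, start: int,
              exon_lengths: list[int], intron_length: int,
              cds: str) -> GeneModel:
    exons = []
    pos = start
    for length in exon_lengths:
        exons.append((pos, pos + length - 1))
        pos += length + intron_length
    return GeneModel(gene_id=gene_id, supercontig=supercontig, strand=strand,
                     exons=exons, coding_sequence=cds)


@pytest.fixture(scope="session")
def kdr_panel() -> GenePanel:
    """Synthetic VGSC-fragment stand-in: 6 exons of 240 bp; codon 406
    (CDS bases 1216-1218) is TTA and falls in exon 6."""
    rng = np.random.default_rng(20140715)
    cds = random_codons(rng, 480)  # 1440 bases over 6 x 240 bp exons
    cds[405] = "TTA"  # codon 406
    gene = make_gene("VGSC0595", "sc182", "+", start=1000,
                     exon_lengths=[240] * 6, intron_length=80,
                     cds="".join(cds))
    return GenePanel({"sc182": 5000}, [gene], flank_length=150)


@pytest.fixture(scope="session")
def kdr_codon406_site(kdr_panel):
    """Supercontig coordinates of the third base of codon 406."""
    gene = kdr_panel.gene("VGSC0595")
    # codon 406 occupies CDS indices 1215..1217; exon 6 starts at CDS 1200
    exon6_start = gene.exons[5][0]
    return exon6_start + (1217 - 1200)


@pytest.fixture(scope="session")
def p450_minus_panel() -> GenePanel:
    """A minus-strand cytochrome-P450-like gene for strand handling tests.

    Codon 245 of the coding sequence is TTC, so the supercontig (plus
    strand) shows GAA at the mirrored position.
    """
    rng = np.random.default_rng(510)
    cds = random_codons(rng, 300)
    cds[244] = "TTC"
    gene = make_gene("CYP9M10X", "sc510", "-", start=500,
                     exon_lengths=[300, 300, 300], intron_length=60,
                     cds="".join(cds))
    return GenePanel({"sc510": 3000}, [gene], flank_length=150)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced cohort for unit tests: 60 individuals, 20 genes."""
    return SimulationConfig(
        populations=(PopulationSpec("P1", 20, True),
                     PopulationSpec("P2", 20, False),
                     PopulationSpec("P3", 20, False)),
        n_genes=20, n_neutral_snps=80,
        causal_snps=(CausalSnpSpec(gene_index=0, effect=np.log(8.0),
                                   freq=0.3, n_linked=4,
                                   insecticides=("permethrin", "malathion")),),
        duplications=(DuplicationSpec(gene_index=1, copy_ratio=1.6,
                                      carrier_fraction_resistant=0.5),),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """Full study-scale cohort (125 individuals, 122 genes)."""
    return simulate_cohort(SimulationConfig(), seed=7)
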