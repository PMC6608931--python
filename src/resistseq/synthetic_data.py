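"""Synthetic amplicon-panel cohorts with known ground truth.

Emulates the statistical structure of a targeted-resequencing resistance
study: ~125 unrelated individuals drawn from 8 field populations, a
~122-gene panel tiled by overlapping ~200 bp amplicons in two primer
pools, unbalanced binary phenotypes per insecticide, Hardy-Weinberg
genotypes with planted causal SNPs acting on the log-odds of resistance,
planted gene duplications (>= 1.5x depth) enriched in resistant samples,
and negative-binomial read depths with per-sample scale and per-run batch
biases.  Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import DepthMatrix, GenotypeMatrix
from .gene_model import GeneModel, GenePanel

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    size: int
    treated: bool = False


#: Field-study-like sampling design: eight populations totalling 125
#: individuals (the smallest population absorbs the rounding individual).
DEFAULT_POPULATIONS = (
    PopulationSpec("AZU", 8, False),
    PopulationSpec("HCT", 16, True),
    PopulationSpec("HCU", 14, False),
    PopulationSpec("NOT", 13, True),
    PopulationSpec("NOU", 16, False),
    PopulationSpec("TXT", 19, True),
    PopulationSpec("TXU", 19, False),
    PopulationSpec("WCU", 20, False),
)


@dataclass(frozen=True)
class CausalSnpSpec:
    """A planted associated SNP: per-allele effect on the log-odds of
    resistance, baseline alternate-allele frequency (scalar or per
    population), and the insecticides whose phenotype it influences.

    ``n_linked`` > 1 plants a haplotype block: the first site carries the
    phenotype effect and the remaining sites hitchhike in linkage
    disequilibrium with it (each haploid allele copies the causal
    haplotype with probability ``ld_fidelity``, r^2 ~ fidelity^4),
    emulating the correlated SNP clusters a selective sweep leaves in
    targeted panels."""

    gene_index: int
    effect: float
    freq: float | Mapping[str, float] = 0.25
    insecticides: tuple[str, ...] = ("permethrin",)
    n_linked: int = 1
    ld_fidelity: float = 0.95

    def freq_for(self, population: str) -> float:
        if isinstance(self.freq, Mapping):
            return float(self.freq[population])
        return float(self.freq)


@dataclass(frozen=True)
class DuplicationSpec:
    """A planted gene duplication: depth of the gene's amplicons is scaled
    by ``copy_ratio`` in carrier samples, drawn preferentially from the
    resistant group of ``insecticide``."""

    gene_index: int
    copy_ratio: float = 1.5
    carrier_fraction_resistant: float = 0.4
    carrier_fraction_susceptible: float = 0.0
    insecticide: str = "malathion"


@dataclass(frozen=True)
class DepthModel:
    """Negative-binomial depth model.  ``mean_depth`` is reads per amplicon
    per sample; ``dispersion`` is the NB size parameter (variance =
    mu + mu^2/size; Poisson as size -> inf).  Lognormal sigmas:
    ``amplicon_sd`` for per-amplicon efficiency, ``sample_sd`` for
    per-sample library scale, ``batch_sd`` for per-run *amplicon-specific*
    amplification biases (the dominant systematic structure between
    sequencing runs that SVD denoising is meant to strip), and
    ``pool_sd`` for a per-run scalar difference between the two primer
    pools.  ``samples_per_run`` emulates chip batching."""

    mean_depth: float = 60.0
    dispersion: float = 12.0
    amplicon_sd: float = 0.30
    sample_sd: float = 0.25
    batch_sd: float = 0.25
    pool_sd: float = 0.05
    samples_per_run: int = 12


@dataclass
class SimulationConfig:
    populations: tuple[PopulationSpec, ...] = DEFAULT_POPULATIONS
    n_genes: int = 122
    exons_per_gene: int = 3
    exon_length: int = 260
    intron_length: int = 50
    genes_per_supercontig: int = 2
    flank_length: int = 150
    amplicon_length: int = 200
    amplicon_step: int = 100
    n_neutral_snps: int = 500
    neutral_freq_range: tuple[float, float] = (0.05, 0.5)
    region_probs: tuple[float, float, float] = (0.63, 0.18, 0.19)
    causal_snps: tuple[CausalSnpSpec, ...] = (
        CausalSnpSpec(gene_index=0, effect=math.log(8.0), freq=0.25,
                      insecticides=("permethrin",)),
    )
    duplications: tuple[DuplicationSpec, ...] = (
        DuplicationSpec(gene_index=1),
    )
    target_resistant_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "malathion": 90 / 125,
            "permethrin": 106 / 125,
        })
    intercepts: Mapping[str, float] | None = None
    depth: DepthModel = DepthModel()
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or any(p.size <= 0 for p in self.populations):
            raise ValueError("population sizes must be positive")
        if self.n_genes <= 0 or self.exons_per_gene <= 0:
            raise ValueError("panel dimensions must be positive")
        if (self.exon_length * self.exons_per_gene) % 3:
            raise ValueError("total exon length must be a codon multiple")
        for spec in self.duplications:
            if spec.copy_ratio < 1:
                raise ValueError("copy_ratio must be >= 1")
            for frac in (spec.carrier_fraction_resistant,
                         spec.carrier_fraction_susceptible):
                if not 0 <= frac <= 1:
                    raise ValueError("carrier fractions must be in [0, 1]")
        lo, hi = self.neutral_freq_range
        if not (0 <= lo <= hi <= 1) or not 0 <= self.missing_rate <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        for spec in self.causal_snps:
            if not 0 <= spec.gene_index < self.n_genes:
                raise ValueError("causal gene_index out of range")
            if spec.n_linked < 1 or not 0 <= spec.ld_fidelity <= 1:
                raise ValueError("n_linked must be >= 1 and ld_fidelity "
                                 "in [0, 1]")
        for frac in self.target_resistant_fractions.values():
            if not 0 < frac < 1:
                raise ValueError("target resistant fractions must be in (0, 1)")

    @property
    def n_individuals(self) -> int:
        return sum(p.size for p in self.populations)

    @property
    def insecticides(self) -> tuple[str, ...]:
        if self.intercepts is not None:
            return tuple(self.intercepts)
        return tuple(self.target_resistant_fractions)

    def intercept_for(self, insecticide: str) -> float:
        """Baseline log-odds of resistance for one insecticide.

        When not given explicitly, the intercept is calibrated so the
        *expected* marginal resistant fraction under Hardy-Weinberg
        causal-genotype distributions equals the configured target
        (e.g. 106/125 resistant to permethrin); with no causal effects
        this reduces to logit(target).
        """
        if self.intercepts is not None:
            return float(self.intercepts[insecticide])
        target = self.target_resistant_fractions[insecticide]
        specs = [s for s in self.causal_snps
                 if insecticide in s.insecticides]
        if not specs:
            return float(logit(target))
        return _calibrate_intercept(target, specs, self.populations)


def _calibrate_intercept(target: float, specs: Sequence[CausalSnpSpec],
                         populations: Sequence[PopulationSpec]) -> float:
    """Solve for the logistic intercept giving the target marginal
    resistant fraction, averaging over Hardy-Weinberg genotype
    distributions per population."""
    from itertools import product as iproduct

    from scipy.optimize import brentq

    total_n = sum(p.size for p in populations)

    def marginal(b0: float) -> float:
        acc = 0.0
        for pop in populations:
            hw = []
            for s in specs:
                q = s.freq_for(pop.name)
                hw.append(((1 - q) ** 2, 2 * q * (1 - q), q ** 2))
            p_res = 0.0
            for combo in iproduct((0, 1, 2), repeat=len(specs)):
                prob = np.prod([hw[j][d] for j, d in enumerate(combo)])
                eta = b0 + sum(s.effect * d for s, d in zip(specs, combo))
                p_res += prob * expit(eta)
            acc += pop.size * p_res
        return acc / total_n

    return float(brentq(lambda b: marginal(b) - target, -20.0, 20.0,
                        xtol=1e-10))


def sample_table(config: SimulationConfig) -> pd.DataFrame:
    """Sample IDs and population of origin, in population order."""
    rows = []
    i = 1
    for pop in config.populations:
        for _ in range(pop.size):
            rows.append({"sample": f"S{i:03d}", "population": pop.name,
                         "treated": pop.treated})
            i += 1
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# panel and site placement

def build_panel(config: SimulationConfig,
                seed: int | np.random.SeedSequence) -> tuple[GenePanel, pd.DataFrame]:
    """Random gene panel plus its overlapping-amplicon tiling (two pools)."""
    rng = np.random.default_rng(seed)
    genes, amp_rows = [], []
    gap, flank = 400, config.flank_length
    exlen, inlen = config.exon_length, config.intron_length
    for gi in range(config.n_genes):
        contig = f"sc{gi // config.genes_per_supercontig + 1}"
        slot = gi % config.genes_per_supercontig
        span_len = config.exons_per_gene * exlen + (config.exons_per_gene - 1) * inlen
        start = gap + slot * (span_len + 2 * flank + gap)
        exons = []
        pos = start
        for _ in range(config.exons_per_gene):
            exons.append((pos, pos + exlen - 1))
            pos += exlen + inlen
        strand = "+" if rng.random() < 0.5 else "-"
        cds = "".join(rng.choice(_BASES, size=config.exons_per_gene * exlen))
        gene = GeneModel(gene_id=f"GENE{gi:04d}", supercontig=contig,
                         strand=strand, exons=exons, coding_sequence=cds)
        genes.append(gene)
        # tile the flanked span with overlapping amplicons, alternating pools
        lo = start - flank
        hi = exons[-1][1] + flank
        a = 0
        while lo + (a * config.amplicon_step) + config.amplicon_length <= hi:
            s0 = lo + a * config.amplicon_step
            amp_rows.append({
                "amplicon_id": f"{gene.gene_id}_a{a:02d}",
                "supercontig": contig, "start": s0 - 1,  # BED 0-based
                "end": s0 - 1 + config.amplicon_length,
                "gene_id": gene.gene_id,
                "length": config.amplicon_length,
                "pool": a % 2 + 1,
            })
            a += 1
    lengths: dict[str, int] = {}
    for g in genes:
        lengths[g.supercontig] = max(lengths.get(g.supercontig, 0),
                                     g.span[1] + flank + gap)
    panel = GenePanel(lengths, genes, flank_length=flank)
    amplicons = pd.DataFrame(amp_rows).set_index("amplicon_id")
    return panel, amplicons


def _exonic_base(gene: GeneModel, position: int) -> str:
    base = gene.coding_sequence[gene.cds_index(position)]
    return _COMPLEMENT[base] if gene.strand == "-" else base


def place_sites(panel: GenePanel, config: SimulationConfig,
                seed: int | np.random.SeedSequence) -> pd.DataFrame:
    """Choose SNP sites on the panel: causal sites always exonic, neutral
    sites spread over exon/intron/flank with configured proportions.
    Returns site metadata with per-population allele frequencies."""
    rng = np.random.default_rng(seed)
    pops = [p.name for p in config.populations]
    used: set[tuple[str, int]] = set()
    rows = []

    def add_site(gene: GeneModel, region: str, freqs: Mapping[str, float],
                 causal_index: int | None, block_index: int | None = None
                 ) -> None:
        for _ in range(1000):
            if region == "exon":
                s, e = gene.exons[rng.integers(len(gene.exons))]
                pos = int(rng.integers(s, e + 1))
            elif region == "intron":
                pairs = list(zip(gene.exons[:-1], gene.exons[1:]))
                (s1, e1), (s2, _) = pairs[rng.integers(len(pairs))]
                pos = int(rng.integers(e1 + 1, s2))
            else:  # flank
                g0, g1 = gene.span
                if rng.random() < 0.5:
                    pos = int(rng.integers(g0 - panel.flank_length, g0))
                else:
                    pos = int(rng.integers(g1 + 1, g1 + panel.flank_length + 1))
            key = (gene.supercontig, pos)
            if key in used:
                continue
            used.add(key)
            if region == "exon":
                ref = _exonic_base(gene, pos)
            else:
                ref = str(rng.choice(_BASES))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            rows.append({
                "site_id": f"{gene.supercontig}:{pos}",
                "supercontig": gene.supercontig, "position": pos,
                "ref": ref, "alt": alt, "gene_id": gene.gene_id,
                "region": region, "causal_index": causal_index,
                "block_index": block_index,
                **{f"freq_{p}": freqs[p] for p in pops},
            })
            return
        raise RuntimeError("could not place a unique SNP site")

    for ci, spec in enumerate(config.causal_snps):
        gene = panel.genes[spec.gene_index]
        freqs = {p: spec.freq_for(p) for p in pops}
        add_site(gene, "exon", freqs, ci, block_index=ci)
        for _ in range(spec.n_linked - 1):  # hitchhiking LD partners
            add_site(gene, "exon", freqs, None, block_index=ci)

    lo, hi = config.neutral_freq_range
    region_names = ("exon", "intron", "flank")
    for _ in range(config.n_neutral_snps):
        gene = panel.genes[rng.integers(len(panel.genes))]
        region = region_names[rng.choice(3, p=config.region_probs)]
        if config.exons_per_gene < 2 and region == "intron":
            region = "exon"
        freq = float(rng.uniform(lo, hi))
        add_site(gene, region, {p: freq for p in pops}, None)

    df = pd.DataFrame(rows).set_index("site_id")
    return df.sort_values(["supercontig", "position"],
                          key=_natural_contig_key)


def _natural_contig_key(col: pd.Series) -> pd.Series:
    if col.name == "supercontig":
        return col.str.removeprefix("sc").astype(int)
    return col


# ---------------------------------------------------------------------------
# generators

def simulate_genotypes(config: SimulationConfig,
                       seed: int | None = None) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes for a fresh cohort (panel built internally).

    For composable pipelines use :func:`simulate_cohort`, which shares one
    panel across all generators.
    """
    cohort = simulate_cohort(config, seed)
    return cohort.genotypes


def _draw_genotypes(sites: pd.DataFrame, samples: pd.DataFrame,
                    config: SimulationConfig,
                    rng: np.random.Generator) -> GenotypeMatrix:
    pop_names = [p.name for p in config.populations]
    freq_by_pop = sites[[f"freq_{p}" for p in pop_names]].to_numpy()
    pop_col = np.array([pop_names.index(p)
                        for p in samples["population"]])
    dosage = rng.binomial(2, freq_by_pop[:, pop_col]).astype(float)
    # haplotype blocks: linked sites copy the causal haplotype's alleles
    # with probability ld_fidelity, giving within-block LD (r^2 ~ s^4)
    if "block_index" in sites.columns:
        site_pos = {s: i for i, s in enumerate(sites.index)}
        n_samp = len(pop_col)
        for ci, spec in enumerate(config.causal_snps):
            members = sites.index[sites["block_index"] == ci]
            if len(members) == 0:
                continue
            p_vec = freq_by_pop[site_pos[members[0]], pop_col]
            hap = rng.random((2, n_samp)) < p_vec  # causal haplotype alleles
            for m in members:
                is_primary = sites.at[m, "causal_index"] == ci
                if is_primary:
                    alleles = hap
                else:
                    copy = rng.random((2, n_samp)) < spec.ld_fidelity
                    fresh = rng.random((2, n_samp)) < p_vec
                    alleles = np.where(copy, hap, fresh)
                dosage[site_pos[m]] = alleles.sum(axis=0).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan
    dosage_df = pd.DataFrame(dosage, index=sites.index,
                             columns=samples.index)
    meta = sites[["supercontig", "position", "ref", "alt"]].copy()
    return GenotypeMatrix(sites=meta, dosage=dosage_df)


def simulate_phenotypes(genotypes: GenotypeMatrix, sites: pd.DataFrame,
                        config: SimulationConfig,
                        seed: int | np.random.SeedSequence | None = None,
                        samples: pd.DataFrame | None = None,
                        ) -> tuple[pd.DataFrame, dict]:
    """Binary resistant/susceptible labels per insecticide.

    The phenotype model is logistic in causal allele dosage:
    logit P(resistant) = intercept + sum_j beta_j * dosage_j.  With no
    causal effects the intercept alone sets the marginal resistant
    fraction.  Returns the phenotype table and the true per-sample
    resistance probabilities.
    """
    rng = np.random.default_rng(seed)
    if samples is None:
        samples = sample_table(config)
    n = len(samples.index)
    pheno = pd.DataFrame(index=samples.index)
    pheno["population"] = samples["population"]
    probs: dict[str, dict[str, float]] = {}
    causal = sites[sites["causal_index"].notna()]
    for insecticide in config.insecticides:
        eta = np.full(n, config.intercept_for(insecticide))
        for site_id, row in causal.iterrows():
            spec = config.causal_snps[int(row["causal_index"])]
            if insecticide not in spec.insecticides:
                continue
            d = genotypes.dosage.loc[site_id].to_numpy(dtype=float)
            eta = eta + spec.effect * np.nan_to_num(d, nan=0.0)
        p = expit(eta)
        labels = np.where(rng.random(n) < p, "resistant", "susceptible")
        pheno[insecticide] = labels
        probs[insecticide] = dict(zip(samples.index, map(float, p)))
    return pheno, probs


def bioassay_label(percent_dead: float) -> str:
    """Bottle-bioassay classification rule: a family is resistant iff at
    most 80% of its mosquitoes are dead at the diagnostic time."""
    if not 0 <= percent_dead <= 100:
        raise ValueError("percent dead must be in [0, 100]")
    return "resistant" if percent_dead <= 80.0 else "susceptible"


def simulate_bioassay_family(
    p_death_profile: float | Callable[[float], float],
    n_mosquitoes: int = 15,
    diagnostic_time: float = 30.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, str]:
    """Bottle-bioassay outcome for one family.

    ``p_death_profile`` is the probability an individual mosquito is dead
    at the diagnostic time (30 min for permethrin, 45 min for malathion),
    given either as a constant or as a function of time.  The family is
    resistant iff <= 80% are dead at that time, susceptible otherwise.
    """
    if n_mosquitoes <= 0:
        raise ValueError("n_mosquitoes must be positive")
    p = (p_death_profile(diagnostic_time) if callable(p_death_profile)
         else float(p_death_profile))
    if not 0 <= p <= 1:
        raise ValueError("death probability must be in [0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    dead = int(rng.binomial(n_mosquitoes, p))
    percent_dead = 100.0 * dead / n_mosquitoes
    return percent_dead, bioassay_label(percent_dead)


def assign_duplication_carriers(phenotypes: pd.DataFrame, panel: GenePanel,
                                config: SimulationConfig,
                                seed: int | np.random.SeedSequence | None = None,
                                ) -> dict[str, dict]:
    """Pick carrier samples for each planted duplication, by phenotype group."""
    rng = np.random.default_rng(seed)
    out: dict[str, dict] = {}
    for spec in config.duplications:
        gene_id = panel.genes[spec.gene_index].gene_id
        labels = phenotypes[spec.insecticide]
        carriers: list[str] = []
        for group, frac in (("resistant", spec.carrier_fraction_resistant),
                            ("susceptible", spec.carrier_fraction_susceptible)):
            members = list(phenotypes.index[labels == group])
            k = int(round(frac * len(members)))
            if k:
                carriers.extend(rng.choice(members, size=k, replace=False))
        out[gene_id] = {"copy_ratio": float(spec.copy_ratio),
                        "carriers": sorted(carriers)}
    return out


def simulate_depths(config: SimulationConfig,
                    amplicons: pd.DataFrame,
                    samples: pd.DataFrame,
                    duplications: Mapping[str, Mapping] | None = None,
                    seed: int | np.random.SeedSequence | None = None,
                    ) -> DepthMatrix:
    """Negative-binomial per-amplicon read counts.

    mean = depth.mean_depth x amplicon efficiency x sample scale x
    per-run amplicon-specific batch bias x per-run pool factor x copy
    ratio (duplication carriers, on that gene's amplicons only).
    """
    rng = np.random.default_rng(seed)
    dm = config.depth
    n_amp, n_samp = len(amplicons), len(samples)
    amp_eff = rng.lognormal(0.0, dm.amplicon_sd, size=n_amp)
    samp_scale = rng.lognormal(0.0, dm.sample_sd, size=n_samp)
    runs = np.arange(n_samp) // dm.samples_per_run
    n_runs = runs.max() + 1
    pools = amplicons["pool"].to_numpy(dtype=int)
    run_amp = rng.lognormal(0.0, dm.batch_sd, size=(n_runs, n_amp))
    pool_run = rng.lognormal(0.0, dm.pool_sd, size=(n_runs, pools.max() + 1))
    mean = (dm.mean_depth
            * amp_eff[:, None] * samp_scale[None, :]
            * run_amp[runs, :].T
            * pool_run[runs[None, :], pools[:, None] - 1])
    if duplications:
        sample_pos = {s: j for j, s in enumerate(samples.index)}
        gene_ids = amplicons["gene_id"].to_numpy()
        for gene_id, info in duplications.items():
            rows = np.flatnonzero(gene_ids == gene_id)
            cols = [sample_pos[s] for s in info["carriers"] if s in sample_pos]
            if len(rows) and cols:
                mean[np.ix_(rows, cols)] *= float(info["copy_ratio"])
    p = dm.dispersion / (dm.dispersion + mean)
    counts = rng.negative_binomial(dm.dispersion, p)
    counts_df = pd.DataFrame(counts, index=amplicons.index,
                             columns=samples.index)
    return DepthMatrix(amplicons=amplicons, counts=counts_df)


# ---------------------------------------------------------------------------
# orchestrator

@dataclass
class SyntheticCohort:
    config: SimulationConfig
    panel: GenePanel
    amplicons: pd.DataFrame
    sites: pd.DataFrame
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    depths: DepthMatrix
    truth: dict


def simulate_cohort(config: SimulationConfig,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate a full cohort: panel, SNPs, genotypes, phenotypes, depths,
    and the ground-truth record used by recovery tests."""
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    s_panel, s_sites, s_geno, s_pheno, s_dup, s_depth = ss.spawn(6)
    panel, amplicons = build_panel(config, s_panel)
    sites = place_sites(panel, config, s_sites)
    samples = sample_table(config)
    genotypes = _draw_genotypes(sites, samples, config,
                                np.random.default_rng(s_geno))
    phenotypes, probs = simulate_phenotypes(genotypes, sites, config,
                                            s_pheno, samples)
    duplications = assign_duplication_carriers(phenotypes, panel, config, s_dup)
    depths = simulate_depths(config, amplicons, samples, duplications, s_depth)
    causal = sites[sites["causal_index"].notna()]
    truth = {
        "seed": int(seed),
        "causal_snps": [
            {"site_id": site_id,
             "gene_id": row["gene_id"],
             "effect": config.causal_snps[int(row["causal_index"])].effect,
             "insecticides": list(
                 config.causal_snps[int(row["causal_index"])].insecticides),
             "linked_site_ids": list(
                 sites.index[sites["block_index"]
                             == int(row["causal_index"])])}
            for site_id, row in causal.iterrows()],
        "duplications": duplications,
        "phenotype_probs": probs,
    }
    return SyntheticCohort(config=config, panel=panel, amplicons=amplicons,
                           sites=sites, genotypes=genotypes,
                           phenotypes=phenotypes, depths=depths, truth=truth)
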