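"""SNP annotation: region class, codon context, synonymous/nonsynonymous.

A SNP inside an exon of a gene with a known coding sequence gets a codon
number (counting 5'->3' in gene orientation across the concatenated exons),
its position within the codon, the reference and alternate codons in gene
orientation (reverse-complemented for minus-strand genes), the amino acids,
and an effect class.  The canonical worked example is the kdr L1014F
mutation: a TTA->TTT change at codon 406 of the voltage-gated sodium
channel gene, Leu->Phe, nonsynonymous.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .gene_model import GenePanel, GenomicSite, classify_site

EFFECTS = ("synonymous", "nonsynonymous", "stop_gained", "stop_lost")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


@dataclass
class SnpAnnotation:
    """Annotation of one (site, gene, alt allele) combination."""

    site: GenomicSite
    alt_allele: str
    gene_id: str | None
    region: str
    codon_number: int | None = None
    position_in_codon: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    effect: str | None = None
    error: str | None = None


def annotate_snp(
    panel: GenePanel,
    site: GenomicSite,
    alts: Sequence[str] | None = None,
) -> list[SnpAnnotation]:
    """Annotate one site: one record per overlapping gene per alt allele.

    A reference-allele/CDS disagreement is reported as an ``error`` flag on
    the record, never silently; the effect fields are then left unset.
    """
    alts = tuple(alts) if alts is not None else site.alt_alleles
    if not alts:
        raise ValueError(f"{site.site_id}: no alternate alleles to annotate")
    records = []
    for call in classify_site(panel, site):
        for alt in alts:
            records.append(_annotate_one(panel, site, alt, call.region,
                                          call.gene_id))
    return records


def _annotate_one(panel, site, alt, region, gene_id) -> SnpAnnotation:
    ann = SnpAnnotation(site=site, alt_allele=alt, gene_id=gene_id,
                        region=region)
    if region != "exon" or gene_id is None:
        return ann
    gene = panel.gene(gene_id)
    if gene.coding_sequence is None:
        return ann
    if len(site.ref_allele) != 1 or len(alt) != 1:
        ann.error = "indel_not_supported"
        return ann

    cds_idx = gene.cds_index(site.position)
    ref_gene = site.ref_allele if gene.strand == "+" else _revcomp(site.ref_allele)
    alt_gene = alt if gene.strand == "+" else _revcomp(alt)
    if gene.coding_sequence[cds_idx] != ref_gene:
        ann.error = (f"ref_mismatch:CDS[{cds_idx}]="
                     f"{gene.coding_sequence[cds_idx]}!={ref_gene}")
        return ann

    coding_idx = cds_idx - gene.cds_offset
    if coding_idx < 0:
        return ann  # upstream of the reading frame
    codon_number = coding_idx // 3 + 1
    pos_in_codon = coding_idx % 3 + 1
    start = gene.cds_offset + (codon_number - 1) * 3
    ref_codon = gene.coding_sequence[start:start + 3]
    if len(ref_codon) < 3:
        return ann  # trailing partial codon
    alt_codon = (ref_codon[:pos_in_codon - 1] + alt_gene
                 + ref_codon[pos_in_codon:])
    ref_aa, alt_aa = _translate(ref_codon), _translate(alt_codon)
    if alt_aa == ref_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "stop_gained"
    elif ref_aa == "*":
        effect = "stop_lost"
    else:
        effect = "nonsynonymous"

    ann.codon_number = codon_number
    ann.position_in_codon = pos_in_codon
    ann.ref_codon, ann.alt_codon = ref_codon, alt_codon
    ann.ref_aa, ann.alt_aa = ref_aa, alt_aa
    ann.effect = effect
    return ann


def annotate_sites(panel: GenePanel,
                   sites: Iterable[GenomicSite]) -> pd.DataFrame:
    """Annotate many sites into the standard annotation table.

    One row per (site, gene, alt).  For downstream filtering the first
    overlapping gene (panel order) is the reporting row for each site.
    """
    rows = []
    for site in sites:
        for ann in annotate_snp(panel, site):
            rows.append({
                "site_id": site.site_id,
                "supercontig": site.supercontig,
                "position": site.position,
                "ref": site.ref_allele,
                "alt": ann.alt_allele,
                "gene_id": ann.gene_id,
                "region": ann.region,
                "codon_number": ann.codon_number,
                "position_in_codon": ann.position_in_codon,
                "ref_codon": ann.ref_codon,
                "alt_codon": ann.alt_codon,
                "ref_aa": ann.ref_aa,
                "alt_aa": ann.alt_aa,
                "effect": ann.effect,
                "error": ann.error,
            })
    return pd.DataFrame(rows)


def percentage(count: int, total: int) -> tuple[float, bool]:
    """One-decimal percentage; (0.0, True) flags an undefined 0/0 ratio."""
    if total == 0:
        return 0.0, True
    return round(100.0 * count / total, 1), False


@dataclass
class EffectSummary:
    """Per-site synonymous/nonsynonymous breakdown of an exonic SNP list.

    Sites whose alternate alleles have differing effects (one synonymous,
    one nonsynonymous) are classed ``mixed`` and listed in
    ``mixed_effect_sites``; they belong to neither pure class, so the pure
    counts partition the remaining sites.
    """

    n_sites: int
    counts: dict[str, int]
    percentages: dict[str, float]
    mixed_effect_sites: list[str] = field(default_factory=list)
    undefined: bool = False


def summarize_effects(annotations: pd.DataFrame | Iterable[SnpAnnotation],
                      merge_stop: bool = False) -> EffectSummary:
    """Summarize effect classes over the distinct sites of an annotation set.

    ``merge_stop`` folds stop_gained/stop_lost into nonsynonymous, for
    summaries comparable to reports that use only the two classes.
    """
    if not isinstance(annotations, pd.DataFrame):
        annotations = annotate_records_frame(annotations)
    effects_by_site: dict[str, set[str]] = defaultdict(set)
    if len(annotations):
        exonic = annotations[annotations["effect"].notna()]
        for site_id, eff in zip(exonic["site_id"], exonic["effect"]):
            if merge_stop and eff in ("stop_gained", "stop_lost"):
                eff = "nonsynonymous"
            effects_by_site[site_id].add(eff)

    counts = {e: 0 for e in EFFECTS}
    counts["mixed"] = 0
    mixed = []
    for site_id, effs in effects_by_site.items():
        if len(effs) == 1:
            counts[next(iter(effs))] += 1
        else:
            counts["mixed"] += 1
            mixed.append(site_id)
    n_sites = len(effects_by_site)
    percentages = {}
    undefined = n_sites == 0
    for name, count in counts.items():
        percentages[name], _ = percentage(count, n_sites)
    return EffectSummary(n_sites=n_sites, counts=counts,
                         percentages=percentages,
                         mixed_effect_sites=sorted(mixed),
                         undefined=undefined)


def annotate_records_frame(records: Iterable[SnpAnnotation]) -> pd.DataFrame:
    rows = [{"site_id": a.site.site_id, "effect": a.effect} for a in records]
    return pd.DataFrame(rows, columns=["site_id", "effect"])
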