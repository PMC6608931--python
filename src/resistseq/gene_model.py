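"""Gene-panel models and genomic region classification.

The targeted panel is a collection of genes, each a set of exons on a
supercontig (unplaced assembly scaffold), sequenced together with a fixed
flanking window on both ends of the gene.  All external coordinates are
1-based inclusive, reported as ``supercontig:position``; BED interfaces are
0-based half-open as usual.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple

import pandas as pd

VALID_BASES = frozenset("ACGT")

#: region labels emitted by :func:`classify_site`
REGIONS = ("exon", "intron", "flank", "intergenic")


@dataclass(frozen=True)
class GenomicSite:
    """A single-nucleotide site on a supercontig (1-based position)."""

    supercontig: str
    position: int
    ref_allele: str
    alt_alleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for allele in (self.ref_allele, *self.alt_alleles):
            if not allele or set(allele) - VALID_BASES:
                raise ValueError(f"invalid allele {allele!r} at "
                                 f"{self.supercontig}:{self.position}")
        object.__setattr__(self, "alt_alleles", tuple(self.alt_alleles))

    @property
    def site_id(self) -> str:
        return f"{self.supercontig}:{self.position}"


@dataclass
class GeneModel:
    """One gene: strand, ordered exons, and (optionally) its coding sequence.

    ``exons`` are (start, end) pairs in supercontig coordinates, 1-based
    inclusive, sorted and non-overlapping.  ``coding_sequence`` is assembled
    5'->3' in *gene* orientation across the concatenated exons; for a minus
    strand gene it is therefore the reverse complement of the supercontig
    sequence over the exons.  ``cds_offset`` trims leading bases before the
    reading frame starts (default 0 = frame starts at the first exon base).
    """

    gene_id: str
    supercontig: str
    strand: str
    exons: list[tuple[int, int]]
    coding_sequence: str | None = None
    cds_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene has no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = 0
        for start, end in self.exons:
            if start < 1 or end < start:
                raise ValueError(f"{self.gene_id}: bad exon ({start}, {end})")
            if start <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = end
        if self.coding_sequence is not None:
            cds = self.coding_sequence.upper()
            if len(cds) != self.total_exon_length:
                raise ValueError(
                    f"{self.gene_id}: coding sequence length {len(cds)} != "
                    f"total exon length {self.total_exon_length}")
            if (len(cds) - self.cds_offset) % 3:
                raise ValueError(
                    f"{self.gene_id}: CDS length after offset trimming is "
                    "not divisible by 3")
            self.coding_sequence = cds

    @property
    def span(self) -> tuple[int, int]:
        """Gene span: first exon start to last exon end (1-based inclusive)."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def total_exon_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def region_of(self, position: int, flank_length: int) -> str | None:
        """Classify a supercontig position relative to this gene, or None."""
        start, end = self.span
        if start <= position <= end:
            for s, e in self.exons:
                if s <= position <= e:
                    return "exon"
            return "intron"
        if start - flank_length <= position <= end + flank_length:
            return "flank"
        return None

    def cds_index(self, position: int) -> int:
        """0-based index into ``coding_sequence`` for an exonic position.

        Counts 5'->3' in gene orientation (reverse of supercontig order on
        the minus strand).
        """
        offset = 0
        for s, e in self.exons:
            if s <= position <= e:
                idx = offset + (position - s)
                if self.strand == "-":
                    return self.total_exon_length - 1 - idx
                return idx
            offset += e - s + 1
        raise ValueError(
            f"position {position} is not exonic in {self.gene_id}")


class RegionCall(NamedTuple):
    region: str
    gene_id: str | None


@dataclass
class GenePanel:
    """The coordinate authority for annotation: supercontigs plus genes.

    ``supercontigs`` maps scaffold name to length (bp).  Gene IDs are unique;
    every gene's supercontig must be present and its exons within bounds.
    """

    supercontigs: dict[str, int]
    genes: list[GeneModel]
    flank_length: int = 150

    def __post_init__(self) -> None:
        seen: set[str] = set()
        self._by_contig: dict[str, list[GeneModel]] = {}
        for gene in self.genes:
            if gene.gene_id in seen:
                raise ValueError(f"duplicate gene ID {gene.gene_id}")
            seen.add(gene.gene_id)
            if gene.supercontig not in self.supercontigs:
                raise ValueError(
                    f"{gene.gene_id}: unknown supercontig {gene.supercontig}")
            length = self.supercontigs[gene.supercontig]
            if gene.span[1] > length:
                raise ValueError(
                    f"{gene.gene_id}: exon end {gene.span[1]} outside "
                    f"supercontig {gene.supercontig} (length {length})")
            self._by_contig.setdefault(gene.supercontig, []).append(gene)
        self._by_id = {g.gene_id: g for g in self.genes}

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def genes_on(self, supercontig: str) -> list[GeneModel]:
        return self._by_contig.get(supercontig, [])

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def classify_site(panel: GenePanel, site: GenomicSite) -> list[RegionCall]:
    """Label a site as exon/intron/flank per overlapping gene, or intergenic.

    Overlapping genes are allowed: one :class:`RegionCall` is returned per
    gene whose (flank-extended) span contains the site, in panel gene order;
    the first call is the one used for reporting.  A site hit by no gene
    returns a single ``("intergenic", None)`` call.
    """
    if site.supercontig not in panel.supercontigs:
        raise KeyError(f"unknown supercontig {site.supercontig!r}")
    calls = []
    for gene in panel.genes_on(site.supercontig):
        region = gene.region_of(site.position, panel.flank_length)
        if region is not None:
            calls.append(RegionCall(region, gene.gene_id))
    return calls or [RegionCall("intergenic", None)]


# ---------------------------------------------------------------------------
# panel loading

_TSV_COLUMNS = ["gene_id", "supercontig", "strand", "exon_start", "exon_end"]


def load_panel(
    gene_table: str | Path,
    flank_length: int = 150,
    supercontig_lengths: Mapping[str, int] | None = None,
    cds_fasta: str | Path | None = None,
    fmt: str | None = None,
) -> GenePanel:
    """Load a gene panel from a GFF3 file or a 5-column exon TSV.

    The TSV has one row per exon with columns
    ``gene_id  supercontig  strand  exon_start  exon_end`` (1-based
    inclusive, matching the GFF3 convention).  If ``supercontig_lengths``
    is not given, each supercontig's length is taken as the furthest exon
    end plus the flank length (enough for classification).  ``cds_fasta``
    optionally supplies coding sequences keyed by gene ID.
    """
    gene_table = Path(gene_table)
    if fmt is None:
        fmt = "gff3" if gene_table.suffix.lower() in {".gff", ".gff3"} else "tsv"
    if fmt == "gff3":
        records = _read_gff3(gene_table)
    elif fmt == "tsv":
        records = _read_exon_tsv(gene_table)
    else:
        raise ValueError(f"unknown panel format {fmt!r}")

    cds: dict[str, str] = {}
    if cds_fasta is not None:
        from Bio import SeqIO

        cds = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(str(cds_fasta), "fasta")}

    genes = []
    order_seen: set[str] = set()
    for gene_id in records["gene_id"]:
        if gene_id in order_seen:
            continue
        order_seen.add(gene_id)
        rows = records[records["gene_id"] == gene_id]
        strands = set(rows["strand"])
        if len(strands) != 1:
            raise ValueError(f"{gene_id}: inconsistent strand")
        genes.append(GeneModel(
            gene_id=gene_id,
            supercontig=str(rows["supercontig"].iloc[0]),
            strand=strands.pop(),
            exons=list(zip(rows["exon_start"], rows["exon_end"])),
            coding_sequence=cds.get(gene_id),
        ))

    if supercontig_lengths is None:
        lengths: dict[str, int] = {}
        for gene in genes:
            end = gene.span[1] + flank_length
            lengths[gene.supercontig] = max(lengths.get(gene.supercontig, 0), end)
        supercontig_lengths = lengths
    return GenePanel(dict(supercontig_lengths), genes, flank_length)


def _read_exon_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"supercontig": str})
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def _read_gff3(path: Path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True)
    rows = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        for exon in db.children(gene, featuretype="exon", order_by="start"):
            rows.append({
                "gene_id": gene_id, "supercontig": gene.seqid,
                "strand": gene.strand,
                "exon_start": exon.start, "exon_end": exon.end,
            })
    return pd.DataFrame(rows)


def write_panel_tsv(panel: GenePanel, path: str | Path) -> None:
    """Write the panel as the 5-column exon TSV used by :func:`load_panel`."""
    rows = [
        {"gene_id": g.gene_id, "supercontig": g.supercontig, "strand": g.strand,
         "exon_start": s, "exon_end": e}
        for g in panel.genes for s, e in g.exons
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_cds_fasta(panel: GenePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in panel.genes:
            if gene.coding_sequence is None:
                continue
            fh.write(f">{gene.gene_id}\n")
            seq = gene.coding_sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
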