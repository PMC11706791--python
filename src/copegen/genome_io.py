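"""Genome I/O: FASTA + GFF3 + label files into an in-memory gene table.

All internal coordinates are 0-based half-open. GFF3 is converted from its
1-based inclusive convention at the parsing boundary, and BED output is
0-based half-open natively, so no arithmetic happens downstream of load.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ChromosomeInfo",
    "GeneModel",
    "GenomeBundle",
    "load_genome",
    "extract_cds",
    "write_gene_bed",
    "read_labels",
]

_VALID_CDS = set("ACGTN")


@dataclass(frozen=True)
class ChromosomeInfo:
    """One chromosome: name, length in bp, optional centromere position.

    Centromere positions are user-supplied (e.g. read off a Hi-C contact
    map); nothing in this package infers them.
    """

    name: str
    length: int
    centromere_pos: int | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if self.centromere_pos is not None and not (
            0 < self.centromere_pos <= self.length
        ):
            raise ValueError(
                f"chromosome {self.name}: centromere_pos {self.centromere_pos} "
                f"outside (0, {self.length}]"
            )


@dataclass
class GeneModel:
    """One annotated gene; the unit of every per-gene statistic.

    ``start``/``end`` and ``cds_segments`` are 0-based half-open on the
    chromosome. ``cds_segments`` are sorted by genomic start and belong to
    the representative (longest) transcript. Genes without CDS are kept
    with ``has_cds=False`` so spatial statistics still see them.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    labels: set[str] = field(default_factory=set)
    terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: bad span [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        segs = sorted(self.cds_segments)
        for s, e in segs:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: CDS segment [{s},{e}) outside gene span"
                )
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS segments")
        self.cds_segments = segs

    @property
    def has_cds(self) -> bool:
        return bool(self.cds_segments)

    @property
    def midpoint(self) -> int:
        """Integer midpoint of the gene span; the gene's position for all
        spatial statistics (strand-symmetric, unlike start or CDS start)."""
        return (self.start + self.end) // 2

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)


@dataclass
class GenomeBundle:
    """A genome: chromosomes, genes, and per-chromosome sequences."""

    chromosomes: list[ChromosomeInfo]
    genes: list[GeneModel]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        by_name = {c.name: c for c in self.chromosomes}
        for g in self.genes:
            if g.chrom not in by_name:
                raise ValueError(
                    f"gene {g.gene_id} references unknown chromosome {g.chrom!r}"
                )
            if g.end > by_name[g.chrom].length:
                raise ValueError(
                    f"gene {g.gene_id} extends past the end of {g.chrom} "
                    f"({g.end} > {by_name[g.chrom].length})"
                )

    @property
    def chrom_map(self) -> dict[str, ChromosomeInfo]:
        return {c.name: c for c in self.chromosomes}

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def label_universe(self) -> set[str]:
        return {lab for g in self.genes for lab in g.labels}

    def subset(self, label: str) -> list[GeneModel]:
        """Genes carrying a label tag (e.g. 'ion_transport', 'housekeeping').

        A label absent from the bundle's label universe is an error listing
        the available labels.
        """
        if label not in self.label_universe:
            raise KeyError(
                f"unknown label {label!r}; available labels: "
                f"{sorted(self.label_universe)}"
            )
        return [g for g in self.genes if label in g.labels]


def read_labels(labels_path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV of gene_id <tab> label into a dict of tag sets."""
    out: dict[str, set[str]] = {}
    with open(labels_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene_id, label = line.split("\t")[:2]
            out.setdefault(gene_id, set()).add(label)
    return out


def _representative_cds(db: gffutils.FeatureDB, gene) -> list[tuple[int, int]]:
    """CDS segments of the longest transcript (summed CDS length); for a
    single-transcript or transcript-less gene, all CDS children."""
    transcripts = list(db.children(gene, level=1))
    mrnas = [t for t in transcripts if t.featuretype in ("mRNA", "transcript")]
    if mrnas:
        best: list[tuple[int, int]] = []
        for m in mrnas:
            segs = [
                (c.start - 1, c.end)
                for c in db.children(m, featuretype="CDS")
            ]
            if sum(e - s for s, e in segs) > sum(e - s for s, e in best):
                best = segs
        return sorted(best)
    return sorted(
        (c.start - 1, c.end) for c in db.children(gene, featuretype="CDS")
    )


def load_genome(
    fasta_path: str | Path,
    gff3_path: str | Path,
    labels_path: str | Path | None = None,
    centromeres: dict[str, int] | None = None,
) -> GenomeBundle:
    """Load FASTA + GFF3 (+ optional labels TSV) into a :class:`GenomeBundle`.

    Soft-masked (lowercase) bases are uppercased. A gene referencing a
    sequence absent from the FASTA, or a CDS outside its gene span, is a
    hard error naming the offender.
    """
    centromeres = centromeres or {}
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    chromosomes = [
        ChromosomeInfo(name, len(seq), centromeres.get(name))
        for name, seq in sequences.items()
    ]
    labels = read_labels(labels_path) if labels_path else {}

    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=tmp.name,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        for feat in db.features_of_type("gene"):
            if feat.seqid not in sequences:
                raise ValueError(
                    f"gene {feat.id} references unknown chromosome {feat.seqid!r}"
                )
            segs = _representative_cds(db, feat)
            gene_span = (feat.start - 1, feat.end)
            for s, e in segs:
                if s < gene_span[0] or e > gene_span[1]:
                    raise ValueError(
                        f"gene {feat.id}: CDS segment outside gene span"
                    )
            genes.append(
                GeneModel(
                    gene_id=feat.id,
                    chrom=feat.seqid,
                    start=gene_span[0],
                    end=gene_span[1],
                    strand=feat.strand if feat.strand in "+-" else "+",
                    cds_segments=segs,
                    labels=labels.get(feat.id, set()),
                )
            )
    return GenomeBundle(chromosomes=chromosomes, genes=genes, sequences=sequences)


def extract_cds(bundle: GenomeBundle, gene_id: str) -> str:
    """Concatenated representative CDS of a gene, 5'→3'.

    Plus-strand genes concatenate segments in genomic order; minus-strand
    genes reverse-complement and concatenate in reverse genomic order.
    N is tolerated in chromosome sequence but not inside CDS.
    """
    gene = bundle.gene(gene_id)
    if not gene.has_cds:
        raise ValueError(f"gene {gene_id} has no CDS segments")
    chrom_seq = bundle.sequences[gene.chrom]
    parts = [chrom_seq[s:e] for s, e in gene.cds_segments]
    seq = "".join(parts)
    bad = set(seq) - _VALID_CDS
    if bad:
        raise ValueError(f"gene {gene_id}: non-ACGTN characters in CDS: {sorted(bad)}")
    if "N" in seq:
        raise ValueError(f"gene {gene_id}: N inside CDS")
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def write_gene_bed(
    bundle: GenomeBundle,
    subset_label: str | None,
    path: str | Path,
    genes: list[GeneModel] | None = None,
) -> int:
    """Write a gene subset as BED6, sorted by chromosome then start.

    Select by label (unknown label raises, listing available labels) or
    pass an explicit ``genes`` list, which may be empty — an empty subset
    writes an empty file and returns 0.
    """
    if genes is None:
        if subset_label is None:
            genes = bundle.genes
        else:
            genes = bundle.subset(subset_label)
    lines = []
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        lines.append(
            f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
        )
    Path(path).write_text("".join(line + "\n" for line in lines))
    return len(lines)
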