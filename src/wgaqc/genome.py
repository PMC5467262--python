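"""Reference-sequence and gene-model utilities.

Homopolymer tract scanning, per-gene homopolymer content, windowed GC
content, and a minimal coding-consequence rule (stop-gained / frameshift /
in-frame / missense / silent / noncoding) used to flag putative
loss-of-function (LOF) variants.

Coordinates are 0-based half-open everywhere in this package; 1-based
coordinates appear only at the VCF boundary (see :mod:`wgaqc.variants`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table

_VALID_BASES = frozenset("ACGT")
STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # {"TAA", "TAG", "TGA"}
_CODON_TABLE = dict(standard_dna_table.forward_table)

LOF_CONSEQUENCES = frozenset({"stop_gained", "frameshift"})


@dataclass(frozen=True)
class ReferenceSequence:
    """A single contig with an uppercase A/C/G/T sequence."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("reference sequence must be non-empty")
        if set(self.seq) - _VALID_BASES:
            bad = sorted(set(self.seq) - _VALID_BASES)
            raise ValueError(f"reference contains non-ACGT characters: {bad}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """A gene as a set of coding exons on one contig.

    Exons are 0-based half-open intervals, sorted and non-overlapping.
    """

    gene_id: str
    contig: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end):
                raise ValueError(f"bad exon interval ({start}, {end})")
            if start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = end
        if self.coding_length < 3:
            raise ValueError("total coding length must be >= 3")

    @property
    def coding_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def coding_sequence(self, ref: ReferenceSequence) -> str:
        """Concatenated exonic sequence on the forward strand."""
        if self.exons[-1][1] > len(ref):
            raise ValueError(f"gene {self.gene_id} exceeds reference bounds")
        return "".join(ref.seq[s:e] for s, e in self.exons)

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def cds_offset(self, pos: int) -> int | None:
        """Offset of a reference position within the coding sequence, or None."""
        off = 0
        for s, e in self.exons:
            if s <= pos < e:
                return off + (pos - s)
            off += e - s
        return None


@dataclass(frozen=True)
class HomopolymerTract:
    """A maximal single-base run of length >= 4 (or the configured minimum)."""

    contig: str
    start: int
    length: int
    base: str

    @property
    def end(self) -> int:
        return self.start + self.length


def scan_homopolymers(
    ref: ReferenceSequence, min_run: int = 4
) -> list[HomopolymerTract]:
    """All maximal single-base runs of length >= ``min_run``, sorted by start.

    Runs are maximal: the bases flanking each reported tract differ from the
    tract base (or are contig ends), so reported tracts never overlap.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    seq = ref.seq
    tracts: list[HomopolymerTract] = []
    n = len(seq)
    i = 0
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            tracts.append(HomopolymerTract(ref.name, i, j - i, seq[i]))
        i = j
    return tracts


def gene_homopolymer_content(
    gene: GeneModel, ref: ReferenceSequence, min_run: int = 4
) -> tuple[float, float]:
    """(G/C tracts per exonic bp, A/T tracts per exonic bp) for one gene.

    Tracts are counted within the concatenated exonic sequence; G and C
    tracts are pooled, as are A and T tracts, and each pooled count is
    divided by the gene's total coding length.
    """
    cds = gene.coding_sequence(ref)
    if not cds:
        raise ValueError(f"gene {gene.gene_id} has a zero-length coding region")
    tracts = scan_homopolymers(ReferenceSequence(gene.gene_id, cds), min_run=min_run)
    n_gc = sum(1 for t in tracts if t.base in "GC")
    n_at = sum(1 for t in tracts if t.base in "AT")
    return n_gc / len(cds), n_at / len(cds)


def window_gc(ref: ReferenceSequence, pos: int, flank: int = 10) -> float:
    """Fraction of G/C bases in the window ``pos +/- flank`` (clipped at ends)."""
    if not 0 <= pos < len(ref):
        raise ValueError(f"position {pos} outside contig {ref.name}")
    lo = max(0, pos - flank)
    hi = min(len(ref), pos + flank + 1)
    window = ref.seq[lo:hi]
    return sum(1 for b in window if b in "GC") / len(window)


def classify_consequence(allele, gene: GeneModel, ref: ReferenceSequence) -> str:
    """Coding consequence of a normalized allele within one gene.

    Indels fully inside the CDS are ``frameshift`` when the length change is
    not divisible by 3, else ``inframe_indel``. CDS SNVs are ``stop_gained``
    when the mutated codon becomes a stop, otherwise ``missense`` or
    ``silent`` by amino-acid identity. Anything outside the CDS — including
    variants straddling an exon boundary, which are deliberately not
    partially evaluated — is ``noncoding``. LOF := {stop_gained, frameshift}.
    """
    start0 = allele.pos - 1  # 1-based VCF position -> 0-based
    if allele.type == "SNV":
        if not gene.contains(start0):
            return "noncoding"
        off = gene.cds_offset(start0)
        assert off is not None
        frame = off % 3
        codon_positions = _codon_positions(gene, off - frame)
        if codon_positions is None:
            return "noncoding"
        codon = "".join(ref.seq[p] for p in codon_positions)
        mutated = codon[:frame] + allele.alt + codon[frame + 1 :]
        if gene.strand == "-":
            codon = _revcomp(codon)
            mutated = _revcomp(mutated)
        if mutated in STOP_CODONS:
            return "stop_gained"
        if codon in STOP_CODONS:
            # stop-lost; treat as missense for this minimal rule
            return "missense"
        return "silent" if _CODON_TABLE[codon] == _CODON_TABLE[mutated] else "missense"

    # Indel: the anchor base sits at start0; the inserted/deleted bases begin
    # at start0 + 1. Require the affected span to lie inside one exon.
    if allele.type == "insertion":
        affected = (start0, start0 + 1)
    else:  # deletion: deleted reference bases are start0+1 .. start0+len
        affected = (start0 + 1, start0 + 1 + allele.indel_len)
    if not _span_in_one_exon(gene, *affected):
        return "noncoding"
    return "inframe_indel" if allele.indel_len % 3 == 0 else "frameshift"


def is_lof(consequence: str) -> bool:
    return consequence in LOF_CONSEQUENCES


def _span_in_one_exon(gene: GeneModel, start: int, end: int) -> bool:
    return any(s <= start and end <= e for s, e in gene.exons)


def _codon_positions(gene: GeneModel, cds_start: int) -> list[int] | None:
    """Reference positions of the codon starting at CDS offset ``cds_start``."""
    if cds_start < 0 or cds_start + 3 > gene.coding_length:
        return None
    positions: list[int] = []
    off = 0
    for s, e in gene.exons:
        length = e - s
        for k in range(cds_start, cds_start + 3):
            if off <= k < off + length:
                positions.append(s + (k - off))
        off += length
    return positions if len(positions) == 3 else None


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# FASTA / BED interfaces


def read_fasta(path) -> list[ReferenceSequence]:
    """Read all contigs from a FASTA file."""
    from Bio import SeqIO

    return [
        ReferenceSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path, refs: Iterable[ReferenceSequence], width: int = 70) -> None:
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.name}\n")
            for i in range(0, len(ref.seq), width):
                fh.write(ref.seq[i : i + width] + "\n")


def read_gene_bed(path) -> list[GeneModel]:
    """Read gene models from BED6 (0-based half-open; one exon per line).

    Lines sharing a name are merged into a multi-exon gene.
    """
    import pandas as pd

    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["contig", "start", "end", "name", "score", "strand"],
        dtype={"contig": str, "name": str, "strand": str},
    )
    genes: list[GeneModel] = []
    for name, grp in df.groupby("name", sort=False):
        exons = sorted(zip(grp["start"].astype(int), grp["end"].astype(int)))
        genes.append(
            GeneModel(
                gene_id=str(name),
                contig=str(grp["contig"].iloc[0]),
                exons=tuple(exons),
                strand=str(grp["strand"].iloc[0]),
            )
        )
    return genes


def write_gene_bed(path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            for s, e in gene.exons:
                fh.write(f"{gene.contig}\t{s}\t{e}\t{gene.gene_id}\t0\t{gene.strand}\n")
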