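"""Reference genomes, gene annotations and codon-level site context.

Mitochondrial references come in two architectures here: the fragmented
louse genome (≈20 circular minichromosomes of 3--4 kb, one to three genes
each) and the typical single-chromosome arthropod mt genome (~14.5 kb coding
region in ticks).  Both are handled uniformly: a :class:`ReferenceSet` of
:class:`ReferenceSequence` records plus a flat list of
:class:`GeneAnnotation` rows.  Coordinates are 1-based inclusive everywhere
a user sees them; circular chromosomes allow origin-spanning genes
(``end < start``), interpreted modulo the chromosome length.

Translation defaults to the invertebrate mitochondrial genetic code
(NCBI translation table 5), in which TGA encodes Trp and AGA/AGG encode Ser.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Sentinel returned by :func:`translate_codon` for codons containing N.
UNKNOWN_AA = "?"
STOP_AA = "*"


class GenomeError(ValueError):
    """Invalid reference, annotation or coordinate input."""


@dataclass(frozen=True)
class ReferenceSequence:
    """A single reference record (minichromosome or whole mt chromosome)."""

    id: str
    sequence: str
    topology: str = "circular"  # circular | linear

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeError(f"reference {self.id!r} has empty sequence")
        if self.topology not in ("circular", "linear"):
            raise GenomeError(f"topology must be circular|linear, got {self.topology!r}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            offset = next(i for i, b in enumerate(self.sequence) if b in bad)
            raise GenomeError(
                f"reference {self.id!r} contains non-IUPAC character "
                f"{self.sequence[offset]!r} at offset {offset}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, pos: int) -> str:
        """Base at 1-based position ``pos``; modular on circular chromosomes."""
        if self.topology == "circular":
            return self.sequence[(pos - 1) % self.length]
        if not 1 <= pos <= self.length:
            raise GenomeError(f"position {pos} outside linear chrom {self.id} (1..{self.length})")
        return self.sequence[pos - 1]


class ReferenceSet:
    """Ordered, id-indexed collection of reference sequences."""

    def __init__(self, sequences: Iterable[ReferenceSequence]):
        self._seqs: dict[str, ReferenceSequence] = {}
        for seq in sequences:
            if seq.id in self._seqs:
                raise GenomeError(f"duplicate reference id {seq.id!r}")
            self._seqs[seq.id] = seq
        if not self._seqs:
            raise GenomeError("reference set is empty")

    def __len__(self) -> int:
        return len(self._seqs)

    def __iter__(self) -> Iterator[ReferenceSequence]:
        return iter(self._seqs.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> ReferenceSequence:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise GenomeError(f"unknown chromosome {chrom!r}") from None

    @property
    def ids(self) -> list[str]:
        return list(self._seqs)

    def to_fasta(self, path: Union[str, Path], line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for seq in self:
                fh.write(f">{seq.id}\n")
                for i in range(0, seq.length, line_width):
                    fh.write(seq.sequence[i : i + line_width] + "\n")


def load_reference_set(path: Union[str, Path], topology: str = "circular") -> ReferenceSet:
    """Load a FASTA file into a :class:`ReferenceSet`.

    Sequences are upper-cased; any character outside {A,C,G,T,N} raises an
    error naming the record and offset.  Duplicate ids are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeError(f"no FASTA records in {path}")
    return ReferenceSet(
        ReferenceSequence(rec.id, str(rec.seq).upper(), topology) for rec in records
    )


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene (1-based inclusive coordinates).

    ``frame_offset`` is the offset of the first complete codon from the
    gene's coding-strand 5' end (protein genes only).  On circular
    chromosomes ``end < start`` denotes an origin-spanning gene.
    ``anticodon_start`` (tRNA only) is the genomic position of the first
    anticodon base on the coding strand.
    """

    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    gene_class: str = "protein"  # protein | rRNA | tRNA
    frame_offset: int = 0
    transl_table: int = 5
    anticodon_start: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeError(f"gene {self.gene}: strand must be + or -, got {self.strand!r}")
        if self.gene_class not in ("protein", "rRNA", "tRNA"):
            raise GenomeError(f"gene {self.gene}: bad gene_class {self.gene_class!r}")
        if self.frame_offset not in (0, 1, 2):
            raise GenomeError(f"gene {self.gene}: frame_offset must be 0|1|2")
        if self.start < 1 or self.end < 1:
            raise GenomeError(f"gene {self.gene}: coordinates are 1-based (start={self.start})")

    def span_length(self, chrom_length: int) -> int:
        if self.end >= self.start:
            return self.end - self.start + 1
        # origin-spanning on a circular chromosome
        return chrom_length - self.start + 1 + self.end

    def contains(self, pos: int, chrom_length: int) -> bool:
        if self.end >= self.start:
            return self.start <= pos <= self.end
        return pos >= self.start or pos <= self.end

    def coding_offset(self, pos: int, chrom_length: int) -> int:
        """0-based offset of ``pos`` along the coding strand from the gene 5' end."""
        if self.strand == "+":
            off = pos - self.start
        else:
            off = self.end - pos
        return off % chrom_length if self.end < self.start else off


ANNOTATION_COLUMNS = [
    "gene", "chrom", "start", "end", "strand",
    "class", "frame_offset", "transl_table", "anticodon_start",
]


def load_annotations(path: Union[str, Path, io.TextIOBase]) -> list[GeneAnnotation]:
    """Read the tab-separated gene table (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    missing = set(ANNOTATION_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise GenomeError(f"annotation file missing columns: {sorted(missing)}")
    anns = []
    for _, d in df.iterrows():  # itertuples mangles the 'class' column name
        acs = d.get("anticodon_start")
        anns.append(
            GeneAnnotation(
                gene=d["gene"],
                chrom=d["chrom"],
                start=int(d["start"]),
                end=int(d["end"]),
                strand=d["strand"],
                gene_class=d["class"],
                frame_offset=0 if pd.isna(d.get("frame_offset")) else int(d["frame_offset"]),
                transl_table=5 if pd.isna(d.get("transl_table")) else int(d["transl_table"]),
                anticodon_start=None if pd.isna(acs) else int(acs),
            )
        )
    return anns


def write_annotations(annotations: Iterable[GeneAnnotation], path: Union[str, Path]) -> None:
    rows = [
        {
            "gene": a.gene, "chrom": a.chrom, "start": a.start, "end": a.end,
            "strand": a.strand, "class": a.gene_class, "frame_offset": a.frame_offset,
            "transl_table": a.transl_table,
            "anticodon_start": "" if a.anticodon_start is None else a.anticodon_start,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


class GeneticCode:
    """A 64-entry codon table; stop codons map to ``*``.

    Default is NCBI table 5 (invertebrate mitochondrial): TGA→W, AGA/AGG→S,
    stops TAA/TAG.
    """

    def __init__(self, table_id: int = 5):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.codon_to_aa: dict[str, str] = dict(table.forward_table)
        for stop in table.stop_codons:
            self.codon_to_aa[stop] = STOP_AA
        assert len(self.codon_to_aa) == 64

    def __repr__(self) -> str:
        return f"GeneticCode(table_id={self.table_id})"


_CODE_CACHE: dict[int, GeneticCode] = {}


def genetic_code(table_id: int = 5) -> GeneticCode:
    if table_id not in _CODE_CACHE:
        _CODE_CACHE[table_id] = GeneticCode(table_id)
    return _CODE_CACHE[table_id]


def translate_codon(codon: str, code: Optional[GeneticCode] = None) -> str:
    """Translate one codon; returns ``?`` for codons containing N, ``*`` for stops."""
    codon = codon.upper()
    if len(codon) != 3:
        raise GenomeError(f"codon must be 3 bases, got {codon!r}")
    if "N" in codon:
        return UNKNOWN_AA
    if code is None:
        code = genetic_code()
    try:
        return code.codon_to_aa[codon]
    except KeyError:
        raise GenomeError(f"invalid codon {codon!r}") from None


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class SiteContext:
    """What a genomic site is, relative to one annotation unit."""

    gene: str
    gene_class: str  # protein | rRNA | tRNA | intergenic
    strand: Optional[str] = None
    codon_number: Optional[int] = None
    codon_position: Optional[int] = None  # 1|2|3
    ref_codon: Optional[str] = None
    anticodon_third: bool = False


INTERGENIC = SiteContext(gene=".", gene_class="intergenic")


def _codon_genomic_positions(ann: GeneAnnotation, codon_index: int, chrom_length: int) -> list[int]:
    """Genomic 1-based positions of codon ``codon_index`` (0-based), in coding-strand order."""
    def wrap(p: int) -> int:
        return (p - 1) % chrom_length + 1

    if ann.strand == "+":
        first = ann.start + ann.frame_offset + 3 * codon_index
        return [wrap(first + i) for i in range(3)]
    first = ann.end - ann.frame_offset - 3 * codon_index
    return [wrap(first - i) for i in range(3)]


def ref_codon_at(ref: ReferenceSequence, ann: GeneAnnotation, codon_index: int) -> str:
    """Reference codon (coding-strand orientation) for a 0-based codon index."""
    positions = _codon_genomic_positions(ann, codon_index, ref.length)
    bases = [ref.base_at(p) for p in positions]
    if ann.strand == "-":
        bases = [COMPLEMENT[b] for b in bases]
    return "".join(bases)


def locate_site(
    chrom: str,
    pos: int,
    annotations: Iterable[GeneAnnotation],
    reference: Optional[ReferenceSet] = None,
) -> list[SiteContext]:
    """Map a genomic site to gene/codon context, one entry per overlapping annotation.

    Protein genes report codon number (1-based) and codon position (1|2|3)
    computed from the coding strand and frame offset; minus-strand genes read
    codons as reverse complements.  tRNA sites report whether the position is
    the third anticodon base when ``anticodon_start`` is annotated.  A site
    outside every annotation returns the intergenic sentinel.
    """
    ref_seq = reference[chrom] if reference is not None else None
    chrom_length = ref_seq.length if ref_seq is not None else None
    contexts: list[SiteContext] = []
    for ann in annotations:
        if ann.chrom != chrom:
            continue
        clen = chrom_length if chrom_length is not None else max(ann.start, ann.end)
        if not ann.contains(pos, clen):
            continue
        if ann.gene_class == "protein":
            off = ann.coding_offset(pos, clen) - ann.frame_offset
            if off < 0:
                contexts.append(SiteContext(ann.gene, "protein", ann.strand))
                continue
            codon_index, codon_pos = divmod(off, 3)
            codon = (
                ref_codon_at(ref_seq, ann, codon_index) if ref_seq is not None else None
            )
            contexts.append(
                SiteContext(
                    gene=ann.gene, gene_class="protein", strand=ann.strand,
                    codon_number=codon_index + 1, codon_position=codon_pos + 1,
                    ref_codon=codon,
                )
            )
        elif ann.gene_class == "tRNA":
            third = False
            if ann.anticodon_start is not None:
                if ann.strand == "+":
                    third = pos == ann.anticodon_start + 2
                else:
                    third = pos == ann.anticodon_start - 2
            contexts.append(
                SiteContext(gene=ann.gene, gene_class="tRNA", strand=ann.strand,
                            anticodon_third=third)
            )
        else:
            contexts.append(SiteContext(gene=ann.gene, gene_class="rRNA", strand=ann.strand))
    return contexts or [INTERGENIC]


# ---------------------------------------------------------------------------
# Amino-acid physicochemical properties

HYDROPHOBIC = frozenset("AVLIMFWCY")
POLAR = frozenset("STNQYCHKRDE")
POSITIVE = frozenset("KRH")
NEGATIVE = frozenset("DE")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class AminoAcidProperties:
    """Per-residue hydropathy / polarity / charge classes (total on the 20 AAs)."""

    hydrophobic: frozenset = HYDROPHOBIC
    polar: frozenset = POLAR
    positive: frozenset = POSITIVE
    negative: frozenset = NEGATIVE

    def hydropathy(self, aa: str) -> str:
        self._check(aa)
        return "hydrophobic" if aa in self.hydrophobic else "hydrophilic"

    def polarity(self, aa: str) -> str:
        self._check(aa)
        return "polar" if aa in self.polar else "nonpolar"

    def charge(self, aa: str) -> str:
        self._check(aa)
        if aa in self.positive:
            return "+"
        if aa in self.negative:
            return "-"
        return "0"

    @staticmethod
    def _check(aa: str) -> None:
        if aa not in AMINO_ACIDS:
            raise GenomeError(f"not a standard amino acid: {aa!r}")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "AminoAcidProperties":
        """Load a TSV with columns aa, hydropathy, polarity, charge."""
        df = pd.read_csv(path, sep="\t")
        got = set(df["aa"])
        if got != AMINO_ACIDS:
            raise GenomeError(f"property table must cover the 20 amino acids; got {sorted(got)}")
        return cls(
            hydrophobic=frozenset(df.loc[df.hydropathy == "hydrophobic", "aa"]),
            polar=frozenset(df.loc[df.polarity == "polar", "aa"]),
            positive=frozenset(df.loc[df.charge == "+", "aa"]),
            negative=frozenset(df.loc[df.charge == "-", "aa"]),
        )
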