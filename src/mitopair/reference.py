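"""Reference model for the human mitochondrial genome.

Owns the rCRS sequence (NC_012920, 16,569 bp), its circular 1-based coordinate
system, the gene/region map, and the vertebrate mitochondrial codon table.

The genome is circular; every coordinate in this package is 1-based inclusive.
Only the control region (D-loop) crosses the origin: its interval runs from
16024 through 16569 and wraps to 576. All other features live inside 1..16569
without wrapping.

The region map is an input, not a constant: the bundled ``regions.tsv`` holds
the standard rCRS annotation, but callers may substitute their own map (e.g.
for a different mitochondrial reference) as long as it follows the same
six-column TSV schema.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

MT_LENGTH = 16569

#: IUPAC nucleotide ambiguity codes mapped to the base sets they denote.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: One- to three-letter amino acid codes ("stop" is spelled out).
AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "stop",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class CoordinateError(ValueError):
    """A position fell outside 1..16569 or outside the requested feature."""


class ConsequenceError(ValueError):
    """A protein-level operation was requested outside a coding gene."""


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("mitopair").joinpath("data", name)))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CodonTable:
    """Vertebrate mitochondrial genetic code (NCBI translation table 2).

    Differs from the standard code at four codons: TGA=Trp, AGA/AGG=stop,
    ATA=Met. Derived from Biopython's table rather than retyped.
    """

    mapping: dict = field(default_factory=dict)
    stop_codons: frozenset = frozenset()

    @classmethod
    def vertebrate_mitochondrial(cls) -> "CodonTable":
        t = unambiguous_dna_by_id[2]
        mapping = dict(t.forward_table)
        for c in t.stop_codons:
            mapping[c] = "*"
        return cls(mapping=mapping, stop_codons=frozenset(t.stop_codons))

    def aa1(self, codon: str) -> str | None:
        """One-letter amino acid ('*' for stop), or None for ambiguous codons."""
        return self.mapping.get(codon)

    def aa3(self, codon: str) -> str | None:
        a = self.aa1(codon)
        return AA3[a] if a is not None else None

    def translate(self, cds: str) -> str:
        """Translate complete codons; ambiguous codons (containing N) become X."""
        return "".join(
            self.mapping.get(cds[i : i + 3], "X") for i in range(0, len(cds) - len(cds) % 3, 3)
        )


@dataclass(frozen=True)
class Region:
    name: str
    category: str  # control | other_noncoding | rRNA | tRNA | protein_coding
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive; end < start means the feature wraps the origin
    strand: str  # H or L
    frame_start: int | None = None  # first position of codon 1 (H-strand genes)

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    @property
    def length(self) -> int:
        if self.wraps:
            return (MT_LENGTH - self.start + 1) + self.end
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end


CATEGORIES = {"control", "other_noncoding", "rRNA", "tRNA", "protein_coding"}


class RegionMap:
    """Ordered collection of rCRS regions with per-position lookup.

    Invariants enforced at load: every position 1..16569 is covered at least
    once; protein-coding entries carry a reading-frame start; each coding
    gene's length is frame-compatible (a remainder of 1 or 2 marks an
    incomplete terminal codon completed by polyadenylation, which is legal).
    """

    def __init__(self, regions: list[Region]):
        self.regions = list(regions)
        by_name = {}
        for r in self.regions:
            if r.category not in CATEGORIES:
                raise ValueError(f"unknown region category {r.category!r} for {r.name}")
            if r.category == "protein_coding" and r.frame_start is None:
                raise ValueError(f"protein-coding region {r.name} lacks a frame_start")
            by_name[r.name] = r
        self.by_name = by_name
        cover = [0] * (MT_LENGTH + 1)
        for r in self.regions:
            rng = (
                list(range(r.start, MT_LENGTH + 1)) + list(range(1, r.end + 1))
                if r.wraps
                else range(r.start, r.end + 1)
            )
            for p in rng:
                cover[p] += 1
        uncovered = [p for p in range(1, MT_LENGTH + 1) if cover[p] == 0]
        if uncovered:
            raise ValueError(f"region map leaves {len(uncovered)} positions uncovered, e.g. {uncovered[:5]}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionMap":
        regions = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["name", "category", "start", "end", "strand", "frame_start"]
            if header != expected:
                raise ValueError(f"region map header must be {expected}, got {header}")
            for line in fh:
                if not line.strip():
                    continue
                name, cat, start, end, strand, fs = line.rstrip("\n").split("\t")
                regions.append(
                    Region(name, cat, int(start), int(end), strand, int(fs) if fs else None)
                )
        return cls(regions)

    @classmethod
    def bundled(cls) -> "RegionMap":
        return cls.from_tsv(_data_path("regions.tsv"))

    def protein_coding(self) -> list[Region]:
        return [r for r in self.regions if r.category == "protein_coding"]

    def regions_at(self, position: int) -> list[Region]:
        if not 1 <= position <= MT_LENGTH:
            raise CoordinateError(f"position {position} outside 1..{MT_LENGTH}")
        return [r for r in self.regions if r.contains(position)]


@dataclass(frozen=True)
class ReferenceGenome:
    """The rCRS sequence plus its region map and codon table."""

    sequence: str
    name: str = "rCRS/NC_012920"
    region_map: RegionMap = None
    codon_table: CodonTable = None

    def __post_init__(self):
        if len(self.sequence) != MT_LENGTH:
            raise ValueError(f"reference must be {MT_LENGTH} bp, got {len(self.sequence)}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"reference alphabet restricted to ACGTN, found {sorted(bad)}")

    @classmethod
    def from_fasta(cls, path: str | Path, region_map: RegionMap | None = None) -> "ReferenceGenome":
        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls(
            sequence=str(rec.seq).upper(),
            region_map=region_map or RegionMap.bundled(),
            codon_table=CodonTable.vertebrate_mitochondrial(),
        )

    @classmethod
    def bundled(cls) -> "ReferenceGenome":
        return cls.from_fasta(_data_path("rCRS.fa"))

    def base(self, position: int) -> str:
        if not 1 <= position <= MT_LENGTH:
            raise CoordinateError(f"position {position} outside 1..{MT_LENGTH}")
        return self.sequence[position - 1]

    def slice(self, start: int, end: int) -> str:
        """Inclusive 1-based slice; end < start wraps the origin."""
        if end < start:
            return self.sequence[start - 1 :] + self.sequence[:end]
        return self.sequence[start - 1 : end]

    def gene_cds(self, gene: str | Region) -> str:
        """Coding-strand CDS of a protein-coding gene (revcomp for L-strand)."""
        r = self.region_map.by_name[gene] if isinstance(gene, str) else gene
        if r.category != "protein_coding":
            raise ConsequenceError(f"{r.name} is not protein-coding")
        seq = self.slice(r.start, r.end)
        return revcomp(seq) if r.strand == "L" else seq


def region_of(position: int, region_map: RegionMap) -> list[tuple[str, str]]:
    """All (region_name, category) pairs containing a 1-based position.

    The control region honours the origin wrap, so positions 16024..16569 and
    1..576 both map to it. Positions inside gene overlaps (MT-ATP8/MT-ATP6,
    MT-ND4L/MT-ND4, and the 1-bp tRNA junctions) return every containing
    region, in map order.
    """
    hits = region_map.regions_at(position)
    if not hits:
        raise CoordinateError(f"position {position} not covered by the region map")
    return [(r.name, r.category) for r in hits]


def codon_context(
    position: int, gene: str, ref: ReferenceGenome, region_map: RegionMap | None = None
) -> tuple[int, int, str]:
    """Locate a position within its gene's reading frame.

    Returns ``(codon_index, offset_in_codon, reference_codon)`` on the coding
    strand. ``codon_index`` is 0-based from the gene start; ``offset_in_codon``
    is 0..2. For L-strand genes the codon and offset refer to the reverse
    complement, so the returned codon is the one actually translated.
    """
    rmap = region_map or ref.region_map
    r = rmap.by_name.get(gene)
    if r is None or r.category != "protein_coding":
        raise ConsequenceError(f"{gene} is not a protein-coding gene")
    if not r.contains(position):
        raise ConsequenceError(f"position {position} not inside {gene}")
    cds = ref.gene_cds(r)
    cds_offset = (r.end - position) if r.strand == "L" else (position - r.start)
    codon_index, offset = divmod(cds_offset, 3)
    codon = cds[3 * codon_index : 3 * codon_index + 3]
    return codon_index, offset, codon


def load_reference(
    fasta: str | Path | None = None, regions: str | Path | None = None
) -> ReferenceGenome:
    """Load a reference genome; defaults to the bundled rCRS and region map."""
    rmap = RegionMap.from_tsv(regions) if regions else RegionMap.bundled()
    if fasta:
        return ReferenceGenome.from_fasta(fasta, region_map=rmap)
    rec = next(SeqIO.parse(str(_data_path("rCRS.fa")), "fasta"))
    return ReferenceGenome(
        sequence=str(rec.seq).upper(),
        region_map=rmap,
        codon_table=CodonTable.vertebrate_mitochondrial(),
    )
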