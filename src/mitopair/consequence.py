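"""Region and protein-consequence annotation of mtDNA variants.

Substitutions in protein-coding genes are translated in frame on the coding
strand (L-strand genes via the reverse complement) with the vertebrate
mitochondrial code; indels whose net length change is not a multiple of three
are frameshifts, resolved to truncating or non-truncating by translating the
mutated gene sequence to its first stop codon. Genes whose annotated ends are
incomplete terminal codons (completed to UAA by polyadenylation, e.g. MT-CYB)
are handled through the region map's coordinates: a stop is premature iff it
appears before the reference gene's terminal codon.

A variant in a gene-overlap interval (MT-ATP8/MT-ATP6, MT-ND4L/MT-ND4) is
annotated against every containing gene; the first-listed gene is the primary
one used in tabulations.

Annotation never trusts the variant's stated reference allele: it is checked
against the rCRS and a disagreement is recorded in ``flags`` as
``ref_mismatch`` while the consequence is still computed from the true
reference codon and the stated alternate. In-frame coding indels get the
effect ``inframe_indel`` (the effect enum needs a non-frameshift outcome for
them) and are never flagged truncating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .reference import (
    CodonTable,
    CoordinateError,
    MT_LENGTH,
    ReferenceGenome,
    Region,
    revcomp,
)
from .variants import Variant, substitution_class

EFFECTS = {
    "noncoding",
    "synonymous",
    "missense",
    "nonsense",
    "frameshift_truncating",
    "frameshift_nontruncating",
    "inframe_indel",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class Consequence:
    """Annotated effect of one variant (primary region first)."""

    region_name: str
    category: str
    effect: str
    aa_ref: str | None = None
    aa_alt: str | None = None
    truncating: bool = False
    codon_index: int | None = None  # 0-based within the primary gene
    all_regions: tuple = ()
    flags: tuple = ()
    #: per-gene effects for the other genes of an overlap interval
    also: tuple = ()

    @property
    def aa_change(self) -> str:
        if self.effect == "synonymous":
            return "Syn"
        if self.effect in ("frameshift_truncating", "frameshift_nontruncating"):
            return "frameshift (stop)" if self.truncating else "frameshift"
        if self.aa_ref and self.aa_alt:
            return f"{self.aa_ref}-{self.aa_alt}"
        return ""


def truncation_scan(
    mutated_cds: str, table: CodonTable, n_ref_codons: int | None = None
) -> tuple[bool, int | None]:
    """Translate codon-by-codon and report a premature stop.

    ``n_ref_codons`` is the reference gene's codon count including an
    incomplete terminal codon; a stop at any earlier codon index is
    premature. When omitted, the mutated sequence's own length is used.
    """
    if not mutated_cds:
        raise ValueError("empty coding sequence")
    terminal = (n_ref_codons if n_ref_codons is not None else -(-len(mutated_cds) // 3)) - 1
    mutated_cds += "A" * (-len(mutated_cds) % 3)  # polyA completion of a partial codon
    for i in range(len(mutated_cds) // 3):
        if mutated_cds[3 * i : 3 * i + 3] in table.stop_codons:
            return (i < terminal), i
    return False, None


def _mutated_gene_seq(v: Variant, gene: Region, ref: ReferenceGenome) -> str:
    """Coding-strand CDS of ``gene`` with the variant applied (clipped to the gene)."""
    s, e = gene.start, gene.end
    seq = list(ref.slice(s, e))
    if v.kind == "substitution":
        seq[v.position - s] = v.alt_allele
    elif v.kind == "deletion":
        for p in range(max(v.position, s), min(v.end, e) + 1):
            seq[p - s] = ""
    else:  # insertion after anchor v.position
        if s <= v.position < e:
            seq[v.position - s] += v.alt_allele[len(v.ref_allele) :]
    out = "".join(seq)
    return revcomp(out) if gene.strand == "L" else out


def _coding_effect(
    v: Variant, gene: Region, ref: ReferenceGenome, table: CodonTable
) -> dict:
    """Effect of a variant within one protein-coding gene."""
    cds = ref.gene_cds(gene)
    n_ref_codons = -(-len(cds) // 3)
    if v.kind == "substitution":
        off = (gene.end - v.position) if gene.strand == "L" else (v.position - gene.start)
        codon_index, pos_in_codon = divmod(off, 3)
        codon = cds[3 * codon_index : 3 * codon_index + 3]
        alt = _COMP[v.alt_allele] if gene.strand == "L" else v.alt_allele
        mut = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1 :]
        if len(codon) < 3:  # incomplete terminal codon, completed to a stop by polyA
            codon += "A" * (3 - len(codon))
            mut += "A" * (3 - len(mut))
        aa_ref, aa_alt = table.aa3(codon), table.aa3(mut)
        if aa_ref is None or aa_alt is None:  # codon containing the rCRS N
            return dict(effect="missense", aa_ref=None, aa_alt=None, truncating=False,
                        codon_index=codon_index)
        if aa_ref == aa_alt:
            effect = "synonymous"
        elif aa_alt == "stop":
            effect = "nonsense"
        else:
            effect = "missense"
        return dict(
            effect=effect, aa_ref=aa_ref, aa_alt=aa_alt,
            truncating=(effect == "nonsense"), codon_index=codon_index,
        )
    # indel
    net = (len(v.alt_allele) - len(v.ref_allele)) if v.kind == "insertion" else -len(
        [p for p in range(v.position, v.end + 1) if gene.contains(p)]
    )
    mutated = _mutated_gene_seq(v, gene, ref)
    if net % 3 == 0:
        return dict(effect="inframe_indel", aa_ref=None, aa_alt=None,
                    truncating=False, codon_index=None)
    premature, stop_idx = truncation_scan(mutated, table, n_ref_codons)
    effect = "frameshift_truncating" if premature else "frameshift_nontruncating"
    return dict(effect=effect, aa_ref=None, aa_alt=None, truncating=premature,
                codon_index=stop_idx)


def annotate(
    v: Variant,
    ref: ReferenceGenome,
    region_map=None,
    table: CodonTable | None = None,
) -> Consequence:
    """Assign region membership and protein-level effect to one variant."""
    rmap = region_map or ref.region_map
    table = table or ref.codon_table
    if not 1 <= v.position <= MT_LENGTH:
        raise CoordinateError(f"variant position {v.position} outside 1..{MT_LENGTH}")
    regions = rmap.regions_at(v.position)
    flags: list[str] = []
    if v.kind == "substitution" and ref.base(v.position) not in ("N", v.ref_allele):
        flags.append("ref_mismatch")
    if v.kind == "deletion" and ref.slice(v.position, v.end) != v.ref_allele:
        flags.append("ref_mismatch")

    coding = [r for r in regions if r.category == "protein_coding"]
    primary = coding[0] if coding else regions[0]
    if not coding:
        return Consequence(
            region_name=primary.name,
            category=primary.category,
            effect="noncoding",
            all_regions=tuple((r.name, r.category) for r in regions),
            flags=tuple(flags),
        )
    eff = _coding_effect(v, primary, ref, table)
    also = tuple(
        (g.name, _coding_effect(v, g, ref, table)["effect"]) for g in coding[1:]
    )
    return Consequence(
        region_name=primary.name,
        category=primary.category,
        all_regions=tuple((r.name, r.category) for r in regions),
        flags=tuple(flags),
        also=also,
        **eff,
    )


#: display grouping used by the summary table: tRNAs are pooled into one row.
_GROUP_ORDER = [
    "Control region", "Other non-coding", "12S rRNA", "16S rRNA", "tRNAs",
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-CYB", "MT-ATP6", "MT-ATP8",
]


def _group_of(c: Consequence) -> str:
    if c.category == "control":
        return "Control region"
    if c.category == "other_noncoding":
        return "Other non-coding"
    if c.category == "tRNA":
        return "tRNAs"
    if c.region_name == "MT-RNR1":
        return "12S rRNA"
    if c.region_name == "MT-RNR2":
        return "16S rRNA"
    return c.region_name


def tabulate_consequences(
    annotated: list[tuple[Variant, Consequence]],
    novel_keys: set | None = None,
) -> pd.DataFrame:
    """Per-region summary table (counts, ts/tv, indels, syn/nonsyn, novel).

    One row per region group plus a Total row; each variant counts once,
    under its primary region. Percentages are of the grand total.
    ``novel_keys`` is an optional set of variant keys to count as novel
    (variants absent from the reported-variant database).
    """
    counters = {g: dict.fromkeys(
        ["n", "transitions", "transversions", "del", "ins", "nonsyn", "syn", "novel"], 0
    ) for g in _GROUP_ORDER}
    total = len(annotated)
    for v, c in annotated:
        g = _group_of(c)
        row = counters[g]
        row["n"] += 1
        cls = substitution_class(v)
        if cls == "transition":
            row["transitions"] += 1
        elif cls == "transversion":
            row["transversions"] += 1
        elif v.kind == "deletion":
            row["del"] += 1
        else:
            row["ins"] += 1
        if c.category == "protein_coding":
            if c.effect == "synonymous":
                row["syn"] += 1
            else:
                row["nonsyn"] += 1
        if novel_keys and v.key in novel_keys:
            row["novel"] += 1
    rows = []
    for g in _GROUP_ORDER:
        row = counters[g]
        rows.append({"region": g, **row,
                     "pct": 100.0 * row["n"] / total if total else 0.0})
    total_row = {"region": "Total", "pct": 100.0 if total else 0.0}
    for k in ["n", "transitions", "transversions", "del", "ins", "nonsyn", "syn", "novel"]:
        total_row[k] = sum(r[k] for r in rows)
    rows.append(total_row)
    return pd.DataFrame(
        rows,
        columns=["region", "n", "pct", "transitions", "transversions", "del",
                 "ins", "nonsyn", "syn", "novel"],
    )
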