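"""Variant calling and somatic classification for paired mtDNA consensus sequences.

A sample is one Sanger-style consensus sequence of the whole mitochondrial
genome (IUPAC ambiguity codes allowed). Calling aligns the sample globally
against the linearized rCRS and reports each difference as one
:class:`Variant`:

* substitution — one base differs; an ambiguity code whose two-base set
  contains the reference base plus one alternate is called as a substitution
  flagged heteroplasmic (the Sanger double peak);
* insertion — reported in anchor notation, e.g. ``302 A-AC`` means a C
  inserted after position 302;
* deletion — anchored at the first deleted base, e.g. ``13475 T-Del``.

Indels are left-normalized within repeat runs so placement is deterministic
regardless of alignment tie-breaking, which matches the conventional
D310-region notation. The full dynamic-programming alignment of two 16.6 kb
genomes is expensive, so calling first chains unique 21-mer anchors shared by
sample and reference and only aligns the short unanchored windows with an
affine-gap global aligner (match +1, mismatch -1, open -4, extend -1); when
anchoring fails the full global alignment is used as fallback.

Somatic classification is a set comparison of the tumor and non-tumor call
sets of one case: a tumor call absent from the matched non-tumor tissue is
somatic; allele identity governs matching, so a shift between heteroplasmy
and homoplasmy of the same allele stays inherited.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

from Bio import Align
from Bio.Align import substitution_matrices

from .reference import IUPAC, MT_LENGTH, ReferenceGenome

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: code for a heteroplasmic base pair {x, y} -> IUPAC letter
AMBIGUITY_OF = {frozenset(v): k for k, v in IUPAC.items() if len(v) == 2}

_ANCHOR_K = 21


class InputError(ValueError):
    """Sequence contains characters outside the IUPAC nucleotide alphabet."""


class QualityError(ValueError):
    """Alignment identity too low for confident consensus-level calling."""


class PairingError(ValueError):
    """Tumor and non-tumor call lists do not belong to the same case."""


@dataclass(frozen=True)
class Variant:
    """One difference versus the rCRS.

    ``position`` is the 1-based rCRS coordinate of the variant anchor: the
    substituted base, the base after which an insertion occurs, or the first
    deleted base. ``ref_allele``/``alt_allele`` follow anchor notation for
    indels (insertion: ref='A', alt='AC'; deletion: ref=deleted run, alt='').
    """

    position: int
    ref_allele: str
    alt_allele: str
    kind: str  # substitution | insertion | deletion
    heteroplasmic: bool = False
    sample_id: str = ""
    tissue: str = ""  # tumor | non_tumor

    def __post_init__(self):
        if self.kind == "substitution":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError(f"substitution alleles must be single bases: {self}")
            if self.ref_allele == self.alt_allele:
                raise ValueError(f"substitution with ref == alt: {self}")
        elif self.kind == "insertion":
            if len(self.alt_allele) <= len(self.ref_allele) or len(self.ref_allele) != 1:
                raise ValueError(f"insertion must extend a 1-base anchor: {self}")
        elif self.kind == "deletion":
            if not self.ref_allele or self.alt_allele != "":
                raise ValueError(f"deletion needs non-empty ref and empty alt: {self}")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")

    @property
    def key(self) -> tuple:
        """Identity for inherited/somatic matching (heteroplasmy ignored)."""
        return (self.position, self.ref_allele, self.alt_allele, self.kind)

    @property
    def end(self) -> int:
        """Last reference position touched (== position for subs/insertions)."""
        if self.kind == "deletion":
            return self.position + len(self.ref_allele) - 1
        return self.position

    @property
    def replacement(self) -> str:
        """Human-readable allele change in the conventional notation."""
        if self.kind == "substitution":
            return f"{self.ref_allele}-{self.alt_allele}"
        if self.kind == "insertion":
            return f"{self.ref_allele}-{self.alt_allele}"
        if len(self.ref_allele) == 1:
            return f"{self.ref_allele}-Del"
        return f"{self.position}-{self.end} Del"


@dataclass
class PairedCallSet:
    """Partition of one case's calls into inherited / somatic / non-tumor-only."""

    sample_id: str
    inherited: list = field(default_factory=list)
    somatic: list = field(default_factory=list)
    non_tumor_only: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# alignment machinery
# ---------------------------------------------------------------------------

def _iupac_matrix() -> substitution_matrices.Array:
    alphabet = "ACGTRYSWKMBDHVN"
    m = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            m[x, y] = 1.0 if set(IUPAC[x]) & set(IUPAC[y]) else -1.0
    return m


def _make_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = _iupac_matrix()
    al.open_gap_score = -4
    al.extend_gap_score = -1
    return al


_ALIGNER = _make_aligner()


import functools


@functools.lru_cache(maxsize=8)  # keeps the reference index hot across calls
def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in seen:
            del seen[km]
            dup.add(km)
        else:
            seen[km] = i
    return seen


def _lis_chain(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain of anchor pairs strictly increasing in the sample coord.

    ``pairs`` must be sorted by reference coordinate. Patience-sorting LIS on
    the sample coordinate keeps only a colinear subset.
    """
    if not pairs:
        return []
    svals = [s for _, s in pairs]
    tails: list[int] = []  # indices into pairs
    prev = [-1] * len(pairs)
    import bisect

    tvals: list[int] = []
    for i, s in enumerate(svals):
        j = bisect.bisect_left(tvals, s)
        if j == len(tvals):
            tvals.append(s)
            tails.append(i)
        else:
            tvals[j] = s
            tails[j] = i
        prev[i] = tails[j - 1] if j > 0 else -1
    chain = []
    i = tails[-1]
    while i != -1:
        chain.append(pairs[i])
        i = prev[i]
    return chain[::-1]


def _anchor_blocks(ref: str, smp: str, k: int = _ANCHOR_K) -> list[tuple[int, int, int]]:
    """Colinear exact-match blocks (ref_start, smp_start, length), 0-based."""
    rk = _unique_kmers(ref, k)
    sk = _unique_kmers(smp, k)
    pairs = sorted((r, sk[km]) for km, r in rk.items() if km in sk)
    chain = _lis_chain(pairs)
    blocks: list[tuple[int, int, int]] = []
    for r, s in chain:
        if blocks:
            r0, s0, ln = blocks[-1]
            if r - s == r0 - s0 and r <= r0 + ln:
                blocks[-1] = (r0, s0, r - r0 + k)
                continue
            if r < r0 + ln or s < s0 + ln:  # conflicting anchor; drop it
                continue
        blocks.append((r, s, k))
    return blocks


def _align_coordinates(ref: str, smp: str) -> list[tuple[str, str]]:
    """Global alignment as a list of (ref_char_or_'-', smp_char_or_'-') columns."""
    blocks = _anchor_blocks(ref, smp)
    anchored = sum(b[2] for b in blocks)
    if anchored < 0.5 * len(ref):  # anchoring failed; fall back to full DP
        aln = next(iter(_ALIGNER.align(ref, smp)))
        return _alignment_to_columns(aln, ref, smp)
    cols: list[tuple[str, str]] = []
    pr = ps = 0
    for r, s, ln in blocks + [(len(ref), len(smp), 0)]:
        seg_r, seg_s = ref[pr:r], smp[ps:s]
        if seg_r or seg_s:
            cols.extend(_align_segment(seg_r, seg_s))
        cols.extend(zip(ref[r : r + ln], smp[s : s + ln]))
        pr, ps = r + ln, s + ln
    return cols


def _align_segment(seg_r: str, seg_s: str) -> list[tuple[str, str]]:
    if not seg_r:
        return [("-", c) for c in seg_s]
    if not seg_s:
        return [(c, "-") for c in seg_r]
    if len(seg_r) == len(seg_s) and len(seg_r) <= 3:
        return list(zip(seg_r, seg_s))
    aln = next(iter(_ALIGNER.align(seg_r, seg_s)))
    return _alignment_to_columns(aln, seg_r, seg_s)


def _alignment_to_columns(aln, ref: str, smp: str) -> list[tuple[str, str]]:
    cols = []
    (rblocks, sblocks) = aln.aligned
    pr = ps = 0
    for (r0, r1), (s0, s1) in zip(rblocks, sblocks):
        cols.extend((c, "-") for c in ref[pr:r0])
        cols.extend(("-", c) for c in smp[ps:s0])
        cols.extend(zip(ref[r0:r1], smp[s0:s1]))
        pr, ps = r1, s1
    cols.extend((c, "-") for c in ref[pr:])
    cols.extend(("-", c) for c in smp[ps:])
    return cols


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def left_normalize(v: Variant, ref: ReferenceGenome) -> Variant:
    """Shift an indel to its leftmost equivalent placement in the rCRS.

    Within a homopolymer or tandem repeat an indel has many equivalent
    placements; the leftmost one is canonical (e.g. a C inserted anywhere in
    the 303..309 C-tract is reported as ``302 A-AC``). Substitutions pass
    through unchanged.
    """
    seq = ref.sequence
    if v.kind == "deletion":
        i = v.position - 1  # 0-based first deleted base
        j = i + len(v.ref_allele)
        while i > 0 and seq[i - 1] == seq[j - 1]:
            i -= 1
            j -= 1
        return replace(v, position=i + 1, ref_allele=seq[i:j])
    if v.kind == "insertion":
        ins = v.alt_allele[len(v.ref_allele) :]
        p = v.position  # anchor: insert after this 1-based position
        while p > 0 and ins[-1] == seq[p - 1]:
            ins = seq[p - 1] + ins[:-1]
            p -= 1
        anchor = seq[p - 1] if p >= 1 else ""
        if p == 0:  # insertion before position 1: anchor on position 1 instead
            p = 1
            anchor = seq[0]
            ins = ins[1:] + ins[:1]
        return replace(v, position=p, ref_allele=anchor, alt_allele=anchor + ins)
    return v


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_variants(
    sample_seq: str,
    ref: ReferenceGenome,
    sample_id: str = "",
    tissue: str = "",
) -> list[Variant]:
    """Call all differences between one consensus sequence and the reference.

    Raises :class:`InputError` for non-IUPAC characters and
    :class:`QualityError` when the sequence length is outside 90-110% of the
    reference or alignment identity falls below 90%. 'N' positions in either
    sequence are no-calls, not variants.
    """
    smp = sample_seq.upper()
    bad = set(smp) - set(IUPAC)
    if bad:
        raise InputError(f"non-IUPAC characters in sample sequence: {sorted(bad)}")
    if not 0.9 * MT_LENGTH <= len(smp) <= 1.1 * MT_LENGTH:
        raise QualityError(
            f"sample length {len(smp)} outside 90-110% of the {MT_LENGTH} bp reference"
        )
    cols = _align_coordinates(ref.sequence, smp)

    matches = sum(
        1 for r, s in cols if r != "-" and s != "-" and (set(IUPAC[r]) & set(IUPAC[s]))
    )
    if matches < 0.9 * MT_LENGTH:
        raise QualityError(f"alignment identity {matches / MT_LENGTH:.1%} below 90%")

    variants: list[Variant] = []
    rpos = 0  # 1-based position of the last consumed reference base
    pend_ins: list[str] = []
    pend_del_start = None
    pend_del: list[str] = []

    def flush_indels():
        nonlocal pend_ins, pend_del_start, pend_del
        if pend_del:
            variants.append(
                Variant(pend_del_start, "".join(pend_del), "", "deletion", False, sample_id, tissue)
            )
            pend_del, pend_del_start = [], None
        if pend_ins:
            anchor_pos = max(rpos, 1)
            anchor = ref.base(anchor_pos)
            variants.append(
                Variant(
                    anchor_pos, anchor, anchor + "".join(pend_ins), "insertion",
                    False, sample_id, tissue,
                )
            )
            pend_ins = []

    for rbase, sbase in cols:
        if rbase != "-" and sbase != "-":
            flush_indels()
            rpos += 1
            if sbase == rbase or rbase == "N" or sbase == "N":
                continue
            sset = IUPAC[sbase]
            if len(sset) == 1:
                variants.append(
                    Variant(rpos, rbase, sbase, "substitution", False, sample_id, tissue)
                )
            elif len(sset) == 2 and rbase in sset:
                alt = sset.replace(rbase, "")
                variants.append(
                    Variant(rpos, rbase, alt, "substitution", True, sample_id, tissue)
                )
            else:
                raise InputError(
                    f"ambiguity code {sbase} at position {rpos} does not denote the "
                    f"reference base plus one alternate"
                )
        elif sbase == "-":  # deletion column
            rpos += 1
            if pend_ins:  # mixed indel run: emit insertion first
                flush_indels()
            if not pend_del:
                pend_del_start = rpos
            pend_del.append(rbase)
        else:  # insertion column
            if pend_del:
                flush_indels()
            pend_ins.append(sbase)
    flush_indels()
    normalized = [left_normalize(v, ref) for v in variants]
    normalized.sort(key=lambda v: (v.position, v.kind, v.alt_allele))
    return normalized


def apply_variants(ref: ReferenceGenome, variants: list[Variant]) -> str:
    """Reconstruct a sample sequence by applying a call set to the reference.

    Heteroplasmic substitutions are written as the IUPAC code of
    {ref, alt}. Variants must not overlap.
    """
    seq = list(ref.sequence)
    marks = [""] * (MT_LENGTH + 2)  # insertion text to place after position i
    for v in sorted(variants, key=lambda x: x.position):
        if v.kind == "substitution":
            if seq[v.position - 1] != v.ref_allele:
                raise ValueError(f"ref mismatch applying {v}")
            if v.heteroplasmic:
                seq[v.position - 1] = AMBIGUITY_OF[frozenset({v.ref_allele, v.alt_allele})]
            else:
                seq[v.position - 1] = v.alt_allele
        elif v.kind == "deletion":
            for i in range(v.position - 1, v.position - 1 + len(v.ref_allele)):
                if seq[i] == "":
                    raise ValueError(f"overlapping deletion at {v}")
                seq[i] = ""
        else:
            marks[v.position] += v.alt_allele[len(v.ref_allele) :]
    out = []
    for i, base in enumerate(seq, start=1):
        out.append(base)
        if marks[i]:
            out.append(marks[i])
    return "".join(out)


# ---------------------------------------------------------------------------
# pair classification and summaries
# ---------------------------------------------------------------------------

def classify_pair(
    tumor_calls: list[Variant], normal_calls: list[Variant]
) -> PairedCallSet:
    """Split a case's calls into inherited, somatic, and non-tumor-only.

    A tumor call is somatic iff no non-tumor call shares its
    (position, ref, alt, kind); the heteroplasmy flag is ignored, so an
    allele that is heteroplasmic in one tissue and homoplasmic in the other
    still matches as inherited.
    """
    t_ids = {v.sample_id for v in tumor_calls if v.sample_id}
    n_ids = {v.sample_id for v in normal_calls if v.sample_id}
    if len(t_ids) > 1 or len(n_ids) > 1 or (t_ids and n_ids and t_ids != n_ids):
        raise PairingError(f"mismatched sample ids: tumor={t_ids}, normal={n_ids}")
    sample_id = next(iter(t_ids | n_ids), "")
    normal_keys = {v.key for v in normal_calls}
    tumor_keys = {v.key for v in tumor_calls}
    cs = PairedCallSet(sample_id=sample_id)
    for v in tumor_calls:
        (cs.inherited if v.key in normal_keys else cs.somatic).append(v)
    cs.non_tumor_only = [v for v in normal_calls if v.key not in tumor_keys]
    return cs


def substitution_class(v: Variant) -> str:
    """transition, transversion, or indel."""
    if v.kind != "substitution":
        return "indel"
    same = (v.ref_allele in PURINES) == (v.alt_allele in PURINES)
    return "transition" if same else "transversion"


def heteroplasmy_summary(calls: list[Variant]) -> dict:
    """Cohort-level heteroplasmy counts.

    Returns the number of distinct heteroplasmic variants (distinct by
    sample, tissue and allele), the number of cases carrying at least one,
    and a per-tissue split.
    """
    het = [v for v in calls if v.heteroplasmic]
    cases = {v.sample_id for v in het}
    split = {
        "tumor": sum(1 for v in het if v.tissue == "tumor"),
        "non_tumor": sum(1 for v in het if v.tissue == "non_tumor"),
    }
    return {
        "n_heteroplasmic_variants": len(het),
        "n_cases_affected": len(cases),
        "per_tissue": split,
    }


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def variants_to_vcf(variants: list[Variant], ref: ReferenceGenome, origins: dict | None = None) -> str:
    """Render calls as minimal VCF 4.2 text (CHROM=chrM, anchor bases for indels)."""
    out = io.StringIO()
    out.write("##fileformat=VCFv4.2\n")
    out.write(f"##contig=<ID=chrM,length={MT_LENGTH}>\n")
    out.write('##INFO=<ID=ORIGIN,Number=1,Type=String,Description="inherited|somatic|non_tumor_only">\n')
    out.write('##INFO=<ID=HET,Number=1,Type=Integer,Description="1 if heteroplasmic">\n')
    out.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="case id">\n')
    out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for v in sorted(variants, key=lambda x: (x.position, x.alt_allele)):
        if v.kind == "substitution":
            pos, r, a = v.position, v.ref_allele, v.alt_allele
        elif v.kind == "insertion":
            pos, r, a = v.position, v.ref_allele, v.alt_allele
        else:  # deletion: VCF anchors on the base before the deleted run
            pos = v.position - 1
            if pos < 1:
                pos = 1
            anchor = ref.base(pos)
            r, a = anchor + v.ref_allele, anchor
        info = [f"HET={int(v.heteroplasmic)}"]
        if origins and v.key in origins:
            info.insert(0, f"ORIGIN={origins[v.key]}")
        if v.sample_id:
            info.append(f"SAMPLE={v.sample_id}")
        out.write(f"chrM\t{pos}\t.\t{r}\t{a}\t.\tPASS\t{';'.join(info)}\n")
    return out.getvalue()


def variants_to_table(variants: list[Variant], origins: dict | None = None):
    """Calls as a pandas DataFrame (one row per variant)."""
    import pandas as pd

    rows = []
    for v in variants:
        rows.append(
            {
                "sample_id": v.sample_id,
                "tissue": v.tissue,
                "position": v.position,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "kind": v.kind,
                "replacement": v.replacement,
                "heteroplasmic": v.heteroplasmic,
                "origin": origins.get(v.key, "") if origins else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "tissue", "position", "ref", "alt", "kind",
            "replacement", "heteroplasmic", "origin",
        ],
    )
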