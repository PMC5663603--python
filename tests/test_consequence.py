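"""Consequence annotation: region/effect calls, truncation scanning, tabulation."""

import numpy as np
import pytest

from mitopair import Variant, annotate, tabulate_consequences, truncation_scan
from mitopair.reference import CoordinateError, revcomp


@pytest.mark.parametrize(
    "v,region,effect,aa_change",
    [
        (Variant(3710, "C", "T", "substitution"), "MT-ND1", "missense", "Ala-Val"),
        (Variant(9253, "G", "A", "substitution"), "MT-CO3", "nonsense", "Trp-stop"),
        (Variant(11929, "T", "C", "substitution"), "MT-ND4", "synonymous", "Syn"),
        (Variant(8628, "C", "CC", "insertion"), "MT-ATP6", "frameshift_truncating",
         "frameshift (stop)"),
        (Variant(13475, "T", "", "deletion"), "MT-ND5", "frameshift_truncating",
         "frameshift (stop)"),
        (Variant(14984, "C", "CA", "insertion"), "MT-CYB", "frameshift_truncating",
         "frameshift (stop)"),
        (Variant(94, "G", "A", "substitution"), "MT-DLOOP", "noncoding", ""),
        (Variant(5705, "A", "G", "substitution"), "MT-TN", "noncoding", ""),
    ],
)
def test_annotate_examples(v, region, effect, aa_change, ref):
    c = annotate(v, ref)
    assert (c.region_name, c.effect, c.aa_change) == (region, effect, aa_change)
    assert c.truncating == (effect in ("nonsense", "frameshift_truncating"))


def test_annotate_flags_reference_mismatch(ref):
    """The published 3877 T-C row: rCRS has G, so the call is flagged, not forced."""
    c = annotate(Variant(3877, "T", "C", "substitution"), ref)
    assert "ref_mismatch" in c.flags
    assert c.aa_change == "Ala-Pro"  # computed from the true reference codon + printed alt


def test_annotate_position_out_of_range(ref):
    with pytest.raises(CoordinateError):
        annotate(Variant(17000, "G", "A", "substitution"), ref)


def test_annotate_overlap_reports_both_genes(ref):
    c = annotate(Variant(8540, "A", "G", "substitution"), ref)
    assert c.region_name == "MT-ATP8"
    assert [g for g, _ in c.also] == ["MT-ATP6"]


def test_inframe_deletion_is_not_frameshift(ref):
    """A 3-bp deletion inside MT-CO1 keeps the frame and is never truncating."""
    v = Variant(6000, ref.slice(6000, 6002), "", "deletion")
    c = annotate(v, ref)
    assert c.effect == "inframe_indel"
    assert not c.truncating


def test_truncation_scan_examples(ref):
    t = ref.codon_table
    nd5 = ref.region_map.by_name["MT-ND5"]
    cds = ref.gene_cds(nd5)
    i = 13475 - nd5.start
    mutated = cds[:i] + cds[i + 1 :]
    premature, idx = truncation_scan(mutated, t, n_ref_codons=-(-len(cds) // 3))
    assert premature and idx < len(cds) // 3 - 1

    cyb = ref.gene_cds("MT-CYB")
    premature, idx = truncation_scan(cyb, t)  # unmutated gene: no internal stop
    assert not premature

    with pytest.raises(ValueError):
        truncation_scan("", t)


def _brute_force_substitution(ref, v):
    """Oracle: rebuild the whole mutated genome, re-extract the gene, diff proteins."""
    genome = ref.sequence[: v.position - 1] + v.alt_allele + ref.sequence[v.position :]
    gene = next(
        r for r in ref.region_map.regions_at(v.position) if r.category == "protein_coding"
    )
    ref_cds = ref.sequence[gene.start - 1 : gene.end]
    mut_cds = genome[gene.start - 1 : gene.end]
    if gene.strand == "L":
        ref_cds, mut_cds = revcomp(ref_cds), revcomp(mut_cds)
    p_ref = ref.codon_table.translate(ref_cds)
    p_mut = ref.codon_table.translate(mut_cds)
    diffs = [(i, a, b) for i, (a, b) in enumerate(zip(p_ref, p_mut)) if a != b]
    if not diffs:
        return "synonymous", None, None
    (i, a, b), = diffs
    if b == "*":
        return "nonsense", a, b
    return "missense", a, b


def test_consequence_matches_brute_force_oracle(ref):
    """Engine vs whole-genome-rebuild translation on random coding substitutions."""
    from mitopair.reference import AA3

    rng = np.random.default_rng(42)
    coding_positions = []
    for r in ref.region_map.protein_coding():
        coding_positions.extend(range(r.start, r.end + 1))
    coding_positions = np.array(sorted(set(coding_positions)))
    n_checked = 0
    for pos in rng.choice(coding_positions, size=300, replace=False):
        pos = int(pos)
        base = ref.base(pos)
        if base == "N":
            continue
        alt = rng.choice([b for b in "ACGT" if b != base])
        v = Variant(pos, base, str(alt), "substitution")
        c = annotate(v, ref)
        effect, aa_ref, aa_alt = _brute_force_substitution(ref, v)
        assert c.effect == effect, (v, c.effect, effect)
        if effect != "synonymous":
            assert (c.aa_ref, c.aa_alt) == (AA3[aa_ref], AA3[aa_alt])
        n_checked += 1
    assert n_checked > 250


def test_tabulate_counts_and_percentages(ref):
    variants = [
        Variant(94, "G", "A", "substitution"),
        Variant(74, "T", "G", "substitution"),
        Variant(9253, "G", "A", "substitution"),
        Variant(11929, "T", "C", "substitution"),
        Variant(13475, "T", "", "deletion"),
        Variant(302, "A", "AC", "insertion"),
    ]
    annotated = [(v, annotate(v, ref)) for v in variants]
    df = tabulate_consequences(annotated, novel_keys={variants[0].key}).set_index("region")
    assert df.loc["Total", "n"] == 6
    assert df.loc["Control region", "n"] == 3
    assert df.loc["Control region", "novel"] == 1
    assert df.loc["MT-CO3", "nonsyn"] == 1
    assert df.loc["MT-ND4", "syn"] == 1
    assert df.loc["MT-ND5", "del"] == 1
    assert df.loc["Control region", "ins"] == 1
    assert df.loc["Total", "transitions"] + df.loc["Total", "transversions"] == 4
    assert df.loc["Control region", "pct"] == pytest.approx(50.0)


def test_tabulate_empty_is_all_zero(ref):
    df = tabulate_consequences([]).set_index("region")
    assert (df["n"] == 0).all()
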