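"""Variant calling, pair classification and substitution classes."""

import numpy as np
import pytest

from mitopair import (
    Variant,
    apply_variants,
    call_variants,
    classify_pair,
    heteroplasmy_summary,
    left_normalize,
    substitution_class,
    variants_to_vcf,
)
from mitopair.variants import InputError, PairingError, QualityError


def test_identity_yields_no_calls(ref):
    assert call_variants(ref.sequence, ref) == []


def test_single_substitution(ref):
    s = ref.sequence[:9252] + "A" + ref.sequence[9253:]
    calls = call_variants(s, ref)
    assert [(v.position, v.ref_allele, v.alt_allele, v.heteroplasmic) for v in calls] == [
        (9253, "G", "A", False)
    ]


def test_48bp_deletion(ref):
    """Removing positions 294-341 is called as one 48-bp deletion."""
    s = ref.sequence[:293] + ref.sequence[341:]
    calls = call_variants(s, ref)
    assert len(calls) == 1
    v = calls[0]
    assert v.kind == "deletion"
    assert len(v.ref_allele) == 48
    assert (v.position, v.end) == (294, 341)


def test_heteroplasmic_iupac_call(ref):
    """An R at 13676 (ref A) is a heteroplasmic A>G substitution."""
    s = ref.sequence[:13675] + "R" + ref.sequence[13676:]
    calls = call_variants(s, ref)
    assert calls == [Variant(13676, "A", "G", "substitution", heteroplasmic=True)]


def test_ambiguity_not_containing_ref_rejected(ref):
    s = ref.sequence[:13675] + "Y" + ref.sequence[13676:]  # ref is A
    with pytest.raises(InputError):
        call_variants(s, ref)


def test_non_iupac_characters_rejected(ref):
    with pytest.raises(InputError):
        call_variants(ref.sequence[:-1] + "Z", ref)


def test_length_out_of_band_rejected(ref):
    with pytest.raises(QualityError):
        call_variants(ref.sequence[: len(ref.sequence) // 2], ref)


def test_insertion_left_normalized_in_d310(ref):
    """A C inserted in the 303-309 C-tract is reported as 302 A-AC."""
    s = ref.sequence[:305] + "C" + ref.sequence[305:]
    calls = call_variants(s, ref)
    assert [(v.position, v.replacement) for v in calls] == [(302, "A-AC")]


def test_left_normalize_deletion_in_repeat(ref):
    # deleting any C of the D310 tract normalizes to the leftmost C (303)
    v = Variant(307, "C", "", "deletion")
    n = left_normalize(v, ref)
    assert n.position == 303


@pytest.mark.parametrize(
    "v,expected",
    [
        (Variant(71, "G", "A", "substitution"), "transition"),
        (Variant(74, "T", "G", "substitution"), "transversion"),
        (Variant(13475, "T", "", "deletion"), "indel"),
        (Variant(302, "A", "AC", "insertion"), "indel"),
    ],
)
def test_substitution_class(v, expected):
    assert substitution_class(v) == expected


def test_classify_pair_identical_lists():
    t = [Variant(100, "G", "A", "substitution", sample_id="c1", tissue="tumor")]
    n = [Variant(100, "G", "A", "substitution", sample_id="c1", tissue="non_tumor")]
    cs = classify_pair(t, n)
    assert cs.somatic == [] and len(cs.inherited) == 1 and cs.non_tumor_only == []


def test_classify_pair_somatic_and_normal_only():
    t = [
        Variant(100, "G", "A", "substitution", sample_id="c1", tissue="tumor"),
        Variant(8628, "C", "CC", "insertion", sample_id="c1", tissue="tumor"),
    ]
    n = [
        Variant(100, "G", "A", "substitution", sample_id="c1", tissue="non_tumor"),
        Variant(200, "T", "C", "substitution", True, sample_id="c1", tissue="non_tumor"),
    ]
    cs = classify_pair(t, n)
    assert [v.position for v in cs.somatic] == [8628]
    assert [v.position for v in cs.non_tumor_only] == [200]
    assert len(cs.inherited) + len(cs.somatic) == len(t)


def test_heteroplasmy_shift_stays_inherited():
    """Heteroplasmic in normal, homoplasmic in tumor: allele identity governs."""
    t = [Variant(5000, "C", "T", "substitution", False, "c1", "tumor")]
    n = [Variant(5000, "C", "T", "substitution", True, "c1", "non_tumor")]
    cs = classify_pair(t, n)
    assert cs.somatic == [] and len(cs.inherited) == 1 and cs.non_tumor_only == []


def test_classify_pair_mismatched_ids():
    t = [Variant(100, "G", "A", "substitution", sample_id="c1")]
    n = [Variant(100, "G", "A", "substitution", sample_id="c2")]
    with pytest.raises(PairingError):
        classify_pair(t, n)


def test_heteroplasmy_summary_counts():
    assert heteroplasmy_summary([]) == {
        "n_heteroplasmic_variants": 0,
        "n_cases_affected": 0,
        "per_tissue": {"tumor": 0, "non_tumor": 0},
    }
    calls = [
        Variant(100, "G", "A", "substitution", True, "c1", "tumor"),
        Variant(200, "T", "C", "substitution", True, "c1", "non_tumor"),
        Variant(300, "G", "A", "substitution", True, "c2", "non_tumor"),
        Variant(400, "G", "A", "substitution", False, "c3", "tumor"),
    ]
    s = heteroplasmy_summary(calls)
    assert s["n_heteroplasmic_variants"] == 3
    assert s["n_cases_affected"] == 2
    assert s["per_tissue"] == {"tumor": 1, "non_tumor": 2}


def _random_variants(ref, rng, n_sub=6, n_indel=2):
    """Non-colliding random planted variants in normalized form."""
    from mitopair.simulate import TRANSITION_OF, _plant_indel

    used = set()
    out = []
    while len(out) < n_sub + n_indel:
        pos = int(rng.integers(100, 16400))
        if ref.base(pos) == "N":
            continue
        if len(out) < n_sub:
            v = Variant(pos, ref.base(pos), TRANSITION_OF[ref.base(pos)], "substitution",
                        heteroplasmic=bool(rng.random() < 0.2))
        else:
            v = left_normalize(_plant_indel(rng, ref, pos, max_len=5), ref)
        span = set(range(v.position - 12, v.end + 13))
        if span & used:
            continue
        used |= span
        out.append(v)
    return sorted(out, key=lambda v: v.position)


@pytest.mark.parametrize("seed", range(8))
def test_round_trip_calling(ref, seed):
    """call(apply(calls)) == calls for random planted-variant genomes."""
    rng = np.random.default_rng(seed)
    planted = _random_variants(ref, rng)
    sample = apply_variants(ref, planted)
    called = call_variants(sample, ref)
    assert [(v.key, v.heteroplasmic) for v in called] == [
        (v.key, v.heteroplasmic) for v in planted
    ]


def test_anchored_calling_matches_full_alignment(ref):
    """The fast anchored path and the full global alignment call identically."""
    from mitopair import variants as vmod

    rng = np.random.default_rng(99)
    planted = _random_variants(ref, rng, n_sub=4, n_indel=2)
    sample = apply_variants(ref, planted)
    fast = call_variants(sample, ref)
    aln = next(iter(vmod._ALIGNER.align(ref.sequence, sample)))
    cols = vmod._alignment_to_columns(aln, ref.sequence, sample)
    # re-run the column walk by monkeypatching the aligner entry point
    orig = vmod._align_coordinates
    vmod._align_coordinates = lambda r, s: cols
    try:
        full = call_variants(sample, ref)
    finally:
        vmod._align_coordinates = orig
    assert [v.key for v in fast] == [v.key for v in full]


def test_vcf_deletion_anchoring(ref):
    """VCF rows for deletions carry the preceding anchor base."""
    v = Variant(294, ref.slice(294, 341), "", "deletion")
    vcf = variants_to_vcf([v], ref)
    line = [l for l in vcf.splitlines() if not l.startswith("#")][0]
    chrom, pos, _, r, a = line.split("\t")[:5]
    assert chrom == "chrM" and int(pos) == 293
    assert r == ref.base(293) + ref.slice(294, 341) and a == ref.base(293)
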