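"""Conservation, consensus pathogenicity and frequency filtering."""

import pytest

from mitopair import (
    KnownVariantTable,
    PredictionPanel,
    SpeciesAlignment,
    Variant,
    consensus_pathogenicity,
    conservation_score,
    frequency_filter,
)
from mitopair.reference import CoordinateError
from mitopair.scores import DELETERIOUS, MISSING, TOLERATED, EvaluationError


def _alignment(columns):
    """Build a 17-species alignment from per-species strings."""
    names = ["Homo sapiens"] + [f"sp{i}" for i in range(1, 17)]
    return SpeciesAlignment(rows=dict(zip(names, columns)), human="Homo sapiens")


def test_conservation_all_match():
    aln = _alignment(["A"] * 17)
    assert conservation_score(1, aln) == (17, 17, 1.0)


def test_conservation_partial_match():
    # 5 of 17 (human + 4 others) carry the human base
    cols = ["A"] * 5 + ["G"] * 12
    assert conservation_score(1, _alignment(cols)) == (5, 17, 5 / 17)


def test_conservation_gaps_do_not_match():
    cols = ["A"] + ["-"] * 16
    assert conservation_score(1, _alignment(cols)) == (1, 17, 1 / 17)


def test_conservation_human_gap_raises():
    cols = ["A-"] + ["AA"] * 16
    aln = _alignment(cols)
    with pytest.raises(CoordinateError):
        conservation_score(2, aln)


def test_conservation_monotone_in_species_removal():
    cols = {"Homo sapiens": "A", "m1": "A", "m2": "A", "x1": "G"}
    aln = SpeciesAlignment(rows=cols, human="Homo sapiens")
    n, total, _ = conservation_score(1, aln)
    smaller = SpeciesAlignment(
        rows={k: v for k, v in cols.items() if k != "m2"}, human="Homo sapiens"
    )
    n2, total2, _ = conservation_score(1, smaller)
    assert (n - n2, total - total2) == (1, 1)


def _panel(n_del, n_tol=None, n_missing=0):
    n_tol = 6 - n_del - n_missing if n_tol is None else n_tol
    verdicts = {}
    for i in range(n_del):
        verdicts[f"p{i}"] = DELETERIOUS
    for i in range(n_tol):
        verdicts[f"t{i}"] = TOLERATED
    for i in range(n_missing):
        verdicts[f"m{i}"] = MISSING
    return PredictionPanel(verdicts)


@pytest.mark.parametrize(
    "n_del,expected",
    [(6, "putative_pathogenic"), (4, "putative_pathogenic"),
     (3, "not_supported"), (0, "not_supported")],
)
def test_consensus_strict_majority(n_del, expected):
    assert consensus_pathogenicity(_panel(n_del)) == expected


def test_consensus_missing_counts_against():
    # 3 deleterious + 3 missing: still below the strict majority of 6
    assert consensus_pathogenicity(_panel(3, n_tol=0, n_missing=3)) == "not_supported"
    assert consensus_pathogenicity(_panel(4, n_tol=0, n_missing=2)) == "putative_pathogenic"


def test_consensus_all_missing_raises():
    with pytest.raises(EvaluationError):
        consensus_pathogenicity(_panel(0, n_tol=0, n_missing=6))


def test_consensus_monotone_in_deleterious_votes():
    for n in range(6):
        lo = consensus_pathogenicity(_panel(n))
        hi = consensus_pathogenicity(_panel(n + 1))
        assert not (lo == "putative_pathogenic" and hi == "not_supported")


def test_frequency_filter_thresholds():
    known = KnownVariantTable({(100, "G", "A"): 0.004, (200, "T", "C"): 0.005})
    assert frequency_filter((100, "G", "A"), known) == "rare"
    assert frequency_filter((200, "T", "C"), known) == "common"  # threshold is strict <
    assert frequency_filter((300, "C", "T"), known) == "unreported"
    assert frequency_filter(Variant(300, "C", "T", "substitution"), known) == "unreported"


def test_known_table_rejects_malformed_frequency():
    with pytest.raises(ValueError):
        KnownVariantTable({(1, "A", "G"): 1.7})


def test_synthetic_species_alignment_consistency(ref):
    """Generated alignment: human row equals the rCRS; scores stay in [0, 1]."""
    from mitopair import synthetic_species_alignment

    aln = synthetic_species_alignment(ref, seed=5)
    assert aln.n_species == 17
    assert aln.rows["Homo sapiens"] == ref.sequence
    for pos in (100, 3307, 9253, 16569):
        n, total, frac = conservation_score(pos, aln)
        assert 1 <= n <= total == 17
        assert 0 < frac <= 1
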