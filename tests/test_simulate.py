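"""Synthetic cohort generator: determinism, truth consistency, planted structure."""

import numpy as np
import pytest

from mitopair import (
    SimConfig,
    apply_variants,
    generate_cohort,
    substitution_class,
    write_cohort,
)
from mitopair.simulate import ConfigError


def test_determinism_byte_identical(tmp_path, ref):
    c1 = generate_cohort(SimConfig(n_cases=5, seed=7), ref=ref)
    c2 = generate_cohort(SimConfig(n_cases=5, seed=7), ref=ref)
    p1 = write_cohort(c1, tmp_path / "a")
    p2 = write_cohort(c2, tmp_path / "b")
    for key in p1:
        assert open(p1[key], "rb").read() == open(p2[key], "rb").read()


def test_different_seeds_differ(ref):
    c1 = generate_cohort(SimConfig(n_cases=5, seed=1), ref=ref)
    c2 = generate_cohort(SimConfig(n_cases=5, seed=2), ref=ref)
    assert any(a.tumor_seq != b.tumor_seq for a, b in zip(c1.records, c2.records))


def test_truth_reproduces_emitted_sequences(small_cohort, ref):
    t = small_cohort.truth
    for rec in small_cohort.records:
        assert apply_variants(ref, t.germline[rec.case_id] + t.somatic[rec.case_id]) == rec.tumor_seq
        assert apply_variants(ref, t.germline[rec.case_id] + t.normal_only[rec.case_id]) == rec.normal_seq


def test_inherited_indels_only_in_noncoding(ref):
    """Planted germline indels never touch protein-coding sequence."""
    cfg = SimConfig(n_cases=40, seed=13, inherited_indel_rate=1.0)
    cohort = generate_cohort(cfg, ref=ref)
    n_indels = 0
    for case, germline in cohort.truth.germline.items():
        for v in germline:
            if v.kind == "substitution":
                continue
            n_indels += 1
            for p in range(v.position, v.end + 1):
                cats = {r.category for r in ref.region_map.regions_at(p)}
                assert "protein_coding" not in cats, (case, v)
    assert n_indels >= 35  # rate 1.0: nearly every case gets one


def test_transition_bias_recovered(ref):
    """With many substitutions the planted ts fraction is recovered closely."""
    cfg = SimConfig(n_cases=60, seed=17, private_inherited_mean=25.0)
    cohort = generate_cohort(cfg, ref=ref)
    classes = []
    for case in cohort.truth.germline:
        for v in (cohort.truth.germline[case] + cohort.truth.somatic[case]):
            c = substitution_class(v)
            if c != "indel":
                classes.append(c)
    # exclude the haplogroup motif sites (fixed transitions) from the check
    frac = np.mean([c == "transition" for c in classes])
    assert frac == pytest.approx(0.898, abs=0.03)


def test_content_targets_in_large_cohort(ref):
    """Planted lognormal contents hit the ratio-of-means and reduced-fraction targets."""
    cfg = SimConfig(n_cases=4000, seed=23)
    t = generate_cohort(cfg, ref=ref).truth
    tv = np.array([t.content[c]["tumor"] for c in t.content])
    nv = np.array([t.content[c]["non_tumor"] for c in t.content])
    assert tv.mean() / nv.mean() == pytest.approx(0.49, abs=0.06)
    assert (tv < nv).mean() == pytest.approx(0.69, abs=0.03)
    assert nv.mean() == pytest.approx(1.45, abs=0.12)


def test_infeasible_config_rejected():
    with pytest.raises(ConfigError, match="fraction_reduced"):
        SimConfig(content_ratio=0.49, fraction_reduced=0.4).validate()
    with pytest.raises(ConfigError, match="must lie in"):
        SimConfig(somatic_case_fraction=1.4).validate()
    with pytest.raises(ConfigError, match="leave mass"):
        SimConfig(control_weight=0.9, nd5_weight=0.2).validate()


def test_somatic_region_weights(ref):
    """About 30% of somatic variants land in the control region, 20% in MT-ND5."""
    cfg = SimConfig(n_cases=600, seed=29, somatic_case_fraction=1.0)
    cohort = generate_cohort(cfg, ref=ref)
    regions = []
    for case, lst in cohort.truth.somatic.items():
        for v in lst:
            names = [n for n, _ in
                     [(r.name, r.category) for r in ref.region_map.regions_at(v.position)]]
            regions.append(names[0])
    regions = np.array(regions)
    assert (regions == "MT-DLOOP").mean() == pytest.approx(0.30, abs=0.04)
    assert (regions == "MT-ND5").mean() == pytest.approx(0.20, abs=0.04)


def test_heteroplasmic_emission_uses_iupac(ref):
    cfg = SimConfig(n_cases=30, seed=31, heteroplasmy_rate=1.0, indel_fraction=0.0,
                    somatic_case_fraction=1.0)
    cohort = generate_cohort(cfg, ref=ref)
    found = 0
    for rec in cohort.records:
        for v in cohort.truth.somatic[rec.case_id]:
            assert v.heteroplasmic
            base = rec.tumor_seq[v.position - 1] if len(rec.tumor_seq) == 16569 else None
            found += 1
    assert found > 0
    ambiguous = set("RYSWKM")
    rec = next(r for r in cohort.records if cohort.truth.somatic[r.case_id]
               and len(r.tumor_seq) == 16569)
    v = cohort.truth.somatic[rec.case_id][0]
    assert rec.tumor_seq[v.position - 1] in ambiguous
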