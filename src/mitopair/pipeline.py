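"""End-to-end cohort analysis: call -> classify -> annotate -> haplogroup ->
copy number -> IHC statistics, with study-style report tables.

The pipeline consumes a cohort directory (paired FASTA with ``<case>_T`` /
``<case>_N`` records, Ct TSV, IHC TSV, covariates TSV) and emits per-variant
tables (TSV + VCF), four summary tables mirroring the study's layout
(inherited-variant overview, somatic variant list, haplogroup distribution,
IHC association) and a machine-readable summary JSON. Given identical inputs
and configuration the outputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .reference import load_reference
from .variants import (
    Variant,
    call_variants,
    classify_pair,
    heteroplasmy_summary,
    substitution_class,
    variants_to_table,
    variants_to_vcf,
)
from .consequence import annotate, tabulate_consequences
from .scores import KnownVariantTable, frequency_filter
from .haplogroups import DiagnosticTable, DegenerateTableError, assign, distribution_test
from .copy_number import cohort_contents, paired_summary, read_ct_table
from .ihc import DegenerateTableError as IHCDegenerateTableError, association_table, combine_score, positivity_summary

log = logging.getLogger("mitopair")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths, fixture overrides and thresholds for one pipeline run."""

    input_dir: Path
    output_dir: Path
    reference_fasta: Path | None = None
    region_map: Path | None = None
    diagnostic_table: Path | None = None
    known_variants: Path | None = None
    seed: int = 0
    rare_frequency: float = 0.005
    age_cutoff: float = 60.0
    size_cutoff_cm: float = 5.0
    calibrate_non_tumor_mean: float | None = None

    def __post_init__(self):
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)


def _read_pairs(fasta: Path) -> dict[str, dict[str, str]]:
    pairs: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(fasta), "fasta"):
        rid = rec.id
        if not (rid.endswith("_T") or rid.endswith("_N")):
            raise PipelineError(f"stage=read: record id {rid!r} must end in _T or _N")
        case, suffix = rid[:-2], rid[-1]
        pairs.setdefault(case, {})[
            "tumor" if suffix == "T" else "non_tumor"
        ] = str(rec.seq).upper()
    for case, d in pairs.items():
        if set(d) != {"tumor", "non_tumor"}:
            raise PipelineError(f"stage=read: case {case} lacks a {'_N' if 'tumor' in d else '_T'} record")
    return pairs


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns the summary dict."""
    t_start = time.time()
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage %-12s +%.1fs", name, time.time() - t_start)

    stage("load")
    ref = load_reference(cfg.reference_fasta, cfg.region_map)
    diag = (DiagnosticTable.from_tsv(cfg.diagnostic_table)
            if cfg.diagnostic_table else DiagnosticTable.bundled())
    known = KnownVariantTable.from_tsv(cfg.known_variants) if cfg.known_variants else None

    fasta = cfg.input_dir / "cohort.fa"
    if not fasta.exists():
        raise PipelineError(f"stage=read: missing input FASTA {fasta}")
    pairs = _read_pairs(fasta)

    stage("call")
    all_calls: list[Variant] = []
    origins: dict = {}
    per_case = {}
    for case in sorted(pairs):
        t_calls = call_variants(pairs[case]["tumor"], ref, case, "tumor")
        n_calls = call_variants(pairs[case]["non_tumor"], ref, case, "non_tumor")
        cs = classify_pair(t_calls, n_calls)
        per_case[case] = cs
        for v in cs.inherited:
            origins[v.key] = "inherited"
        for v in cs.somatic:
            origins[v.key] = "somatic"
        for v in cs.non_tumor_only:
            origins[v.key] = "non_tumor_only"
        all_calls.extend(t_calls)
        all_calls.extend(cs.non_tumor_only)

    stage("annotate")
    annotated = [(v, annotate(v, ref)) for v in all_calls]
    var_df = variants_to_table(all_calls, origins)
    var_df["region"] = [c.region_name for _, c in annotated]
    var_df["effect"] = [c.effect for _, c in annotated]
    var_df["aa_change"] = [c.aa_change for _, c in annotated]
    if known is not None:
        var_df["frequency_class"] = [frequency_filter(v, known) for v, _ in annotated]
    var_df.to_csv(out / "variants.tsv", sep="\t", index=False)
    (out / "variants.vcf").write_text(variants_to_vcf(all_calls, ref, origins))

    # distinct-variant tabulations (each site/allele counted once per origin class)
    def distinct(origin):
        seen, res = set(), []
        for v, c in annotated:
            if origins.get(v.key) == origin and v.key not in seen:
                seen.add(v.key)
                res.append((v, c))
        return res

    inherited = distinct("inherited")
    somatic = distinct("somatic")
    novel_keys = (
        {v.key for v, _ in inherited + somatic
         if frequency_filter(v, known) == "unreported"}
        if known is not None else None
    )
    table1 = tabulate_consequences(inherited, novel_keys)
    table1.to_csv(out / "table1_inherited.tsv", sep="\t", index=False, float_format="%.2f")
    somatic_rows = []
    for v, c in somatic:
        somatic_rows.append({
            "region": c.region_name, "position": v.position,
            "replacement": v.replacement, "aa_change": c.aa_change,
            "effect": c.effect, "truncating": c.truncating,
            "heteroplasmic": v.heteroplasmic,
            "flags": ",".join(c.flags),
        })
    pd.DataFrame(somatic_rows).to_csv(out / "table2_somatic.tsv", sep="\t", index=False)

    stage("haplogroup")
    hg_calls = {case: assign(per_case[case].inherited, diag) for case in sorted(per_case)}
    has_somatic = [bool(per_case[c].somatic) for c in sorted(per_case)]
    hg_df = pd.DataFrame(
        [{"case": c, "haplogroup": h.haplogroup, "macro": h.macro,
          "n_matched": h.n_matched, "n_defining": h.n_defining}
         for c, h in hg_calls.items()]
    )
    hg_df.to_csv(out / "table3_haplogroups.tsv", sep="\t", index=False)
    calls_list = list(hg_calls.values())
    hg_tests = {}
    try:
        chi2, df_, p = distribution_test(calls_list)
        hg_tests["macro_balance"] = {"chi_square": chi2, "df": df_, "P": p}
    except DegenerateTableError as e:
        hg_tests["macro_balance"] = {"error": str(e)}
    try:
        chi2, df_, p = distribution_test(calls_list, subset=has_somatic)
        hg_tests["somatic_vs_macro"] = {"chi_square": chi2, "df": df_, "P": p}
    except DegenerateTableError as e:
        hg_tests["somatic_vs_macro"] = {"error": str(e)}

    stage("copynumber")
    cn_summary = None
    ct_path = cfg.input_dir / "ct_values.tsv"
    if ct_path.exists():
        contents = cohort_contents(read_ct_table(ct_path), cfg.calibrate_non_tumor_mean)
        cn_summary = paired_summary(contents)
        pd.DataFrame([{"case": c.case_id, "tissue": c.tissue, "value": c.value}
                      for c in contents]).to_csv(out / "relative_content.tsv", sep="\t", index=False)

    stage("ihc")
    ihc_summary = None
    ihc_path = cfg.input_dir / "ihc_scores.tsv"
    cov_path = cfg.input_dir / "covariates.tsv"
    if ihc_path.exists() and cov_path.exists():
        ihc = pd.read_csv(ihc_path, sep="\t").set_index("case")
        cov = pd.read_csv(cov_path, sep="\t").set_index("case")
        cases = sorted(set(ihc.index) & set(cov.index))
        calls = [combine_score(int(ihc.loc[c, "intensity"]), int(ihc.loc[c, "area_grade"])).call
                 for c in cases]
        grades = [str(cov.loc[c, "ed_grade"]) for c in cases]
        ihc_summary = {"positivity": positivity_summary(calls, grades)}
        dichotomies = {
            "age": [float(cov.loc[c, "age"]) >= cfg.age_cutoff for c in cases],
            "gender_female": [str(cov.loc[c, "gender"]) == "female" for c in cases],
            "ed_grade_III_IV": [str(cov.loc[c, "ed_grade"]) in ("III", "IV") for c in cases],
            "tumor_size": [float(cov.loc[c, "tumor_size_cm"]) > cfg.size_cutoff_cm for c in cases],
        }
        assoc_rows = []
        for name, mask in dichotomies.items():
            try:
                res = association_table(calls, mask)
                ihc_summary[name] = res
                assoc_rows.append({"variable": name, **{k: res[k] for k in
                                   ("chi_square", "P", "P_yates", "P_fisher", "odds_ratio")}})
            except IHCDegenerateTableError as e:
                ihc_summary[name] = {"error": str(e)}
        pd.DataFrame(assoc_rows).to_csv(out / "table4_ihc.tsv", sep="\t", index=False)

    stage("summarize")
    n_cases = len(pairs)
    som_cases = sum(1 for c in per_case.values() if c.somatic)
    subs = [v for v, _ in inherited + somatic if v.kind == "substitution"]
    ts = sum(1 for v in subs if substitution_class(v) == "transition")
    tv = len(subs) - ts
    het = heteroplasmy_summary(all_calls)
    summary = {
        "n_cases": n_cases,
        "n_inherited_variants": len(inherited),
        "n_somatic_variants": len(somatic),
        "somatic_case_fraction": som_cases / n_cases if n_cases else None,
        "n_substitution_sites": len(subs),
        "transition_fraction": ts / len(subs) if subs else None,
        "transversion_fraction": tv / len(subs) if subs else None,
        "heteroplasmy": het,
        "haplogroup_tests": hg_tests,
        "copy_number": cn_summary,
        "ihc": ihc_summary,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    stage("done")
    return summary
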