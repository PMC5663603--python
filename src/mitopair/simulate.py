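"""Synthetic paired-cohort generator with ground truth for recovery testing.

Emulates the statistical structure the analysis assumes: 86 cases, each with
a tumor and a non-tumor consensus mtDNA sequence derived from the rCRS by
planting haplogroup-defining inherited variants, private germline variants
and tumor-only somatic variants; qPCR Ct tables whose exponentiation yields
lognormal relative contents with a configured tumor/non-tumor ratio of means
and fraction of reduced pairs; and IHC score plus covariate tables with a
configurable TFAM-size association.

Defaults are the study's stated cohort conditions: somatic variants in 40.7%
of cases (1-3 each), 89.8% of substitutions transitions, somatic placement
weighted toward the control region (0.30) and MT-ND5 (0.20), a content ratio
of 0.49 with 69% of pairs reduced, and 81.4% IHC positivity with an
odds-ratio of about 3.65 between tumor size > 5 cm and positivity (the value
implied by the study's printed 2x2 cells).

Content model. Per-pair contents are lognormal with a common log-scale
standard deviation sigma and log-mean difference ln(ratio); sigma is solved
from the reduced fraction F via sigma = ln(1/ratio) / (sqrt(2) *
Phi^-1(F)), which makes the ratio of group means and the reduced fraction
simultaneously attainable (a per-pair-ratio model cannot satisfy both; see
docs/methods.md). Infeasible target pairs (e.g. ratio < 1 with F <= 0.5)
raise :class:`ConfigError`.

Randomness is split into one child stream per output facet (sequence, copy
number, IHC, covariates) spawned from the master seed, so adding a facet
never perturbs the others, and generation is byte-deterministic given the
seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats as _st

from .reference import MT_LENGTH, ReferenceGenome, load_reference
from .variants import AMBIGUITY_OF, Variant, apply_variants, left_normalize
from .haplogroups import DiagnosticTable
from .scores import SpeciesAlignment
from .ihc import combine_score

TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS_OF = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


class ConfigError(ValueError):
    """A simulation parameter set violates a stated constraint."""


@dataclass
class SimConfig:
    """Cohort simulation parameters (defaults = the study's stated conditions)."""

    n_cases: int = 86
    seed: int = 0
    # --- sequence facet ---
    somatic_case_fraction: float = 0.407
    somatic_per_case: tuple = (1, 3)  # uniform inclusive range
    control_weight: float = 0.30
    nd5_weight: float = 0.20
    ts_fraction: float = 0.898
    indel_fraction: float = 0.15  # among somatic variants (7/46 in the study)
    heteroplasmy_rate: float = 0.022  # somatic heteroplasmy (1/46)
    normal_only_rate: float = 0.058  # cases with a non-tumor-only heteroplasmic call (5/86)
    private_inherited_mean: float = 10.0  # Poisson mean of private germline substitutions
    inherited_indel_rate: float = 0.186  # cases with one small non-coding germline indel (16/86)
    haplogroup_freqs: dict = field(default_factory=lambda: {
        "D": 18, "G": 4, "M7": 14, "M8": 5, "M12": 1,
        "A": 8, "N9": 5, "R9": 20, "R11": 2, "B": 8, "H2": 1,
    })
    # --- copy-number facet ---
    content_ratio: float = 0.49  # target tumor/non-tumor ratio of group means
    fraction_reduced: float = 0.69  # target P(tumor < non-tumor)
    non_tumor_mean: float = 1.45
    ct_noise_sd: float = 0.05  # per-replicate Ct noise, cycles
    ct_nuc_mean: float = 20.0
    ct_nuc_sd: float = 1.5
    n_replicates: int = 3
    # --- IHC / covariate facet ---
    ihc_positivity: float = 0.814
    tfam_size_or: float = 3.65  # odds ratio of positivity, size > 5 cm vs <= 5 cm
    large_tumor_fraction: float = 0.407  # P(size > 5 cm), 35/86
    age_mean: float = 55.3
    age_sd: float = 11.0
    male_fraction: float = 0.802  # 69/86
    ed_grade_freqs: dict = field(default_factory=lambda: {"I": 10, "II": 61, "III": 14, "IV": 1})

    def validate(self) -> None:
        fracs = {
            "somatic_case_fraction": self.somatic_case_fraction,
            "ts_fraction": self.ts_fraction,
            "indel_fraction": self.indel_fraction,
            "heteroplasmy_rate": self.heteroplasmy_rate,
            "normal_only_rate": self.normal_only_rate,
            "inherited_indel_rate": self.inherited_indel_rate,
            "ihc_positivity": self.ihc_positivity,
            "large_tumor_fraction": self.large_tumor_fraction,
            "fraction_reduced": self.fraction_reduced,
            "male_fraction": self.male_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.control_weight + self.nd5_weight >= 1.0:
            raise ConfigError("control_weight + nd5_weight must leave mass for other regions")
        if self.content_ratio <= 0:
            raise ConfigError("content_ratio must be positive")
        if self.content_ratio < 1.0 and self.fraction_reduced <= 0.5:
            raise ConfigError(
                "infeasible targets: a tumor/non-tumor ratio of means below 1 requires "
                f"fraction_reduced > 0.5 (got ratio={self.content_ratio}, "
                f"fraction_reduced={self.fraction_reduced})"
            )
        if self.content_ratio > 1.0 and self.fraction_reduced >= 0.5:
            raise ConfigError(
                "infeasible targets: a ratio of means above 1 requires fraction_reduced < 0.5"
            )

    def content_log_sd(self) -> float:
        """Per-tissue lognormal sigma solved from (content_ratio, fraction_reduced)."""
        if math.isclose(self.content_ratio, 1.0):
            return 0.35  # ratio 1: dispersion unconstrained; a moderate default
        z = _st.norm.ppf(self.fraction_reduced)
        tau = abs(math.log(self.content_ratio)) / abs(z)
        return tau / math.sqrt(2.0)


@dataclass
class CohortRecord:
    """One case's full synthetic record."""

    case_id: str
    tumor_seq: str
    normal_seq: str
    haplogroup: str
    ct_rows: list  # raw replicate rows (tissue, target, replicate, ct)
    intensity: int
    area_grade: int
    age: float
    gender: str
    ed_grade: str
    tumor_size_cm: float


@dataclass
class SyntheticTruth:
    """Planted ground truth that exactly generates the emitted cohort files."""

    germline: dict  # case_id -> list of Variant
    somatic: dict  # case_id -> list of Variant
    normal_only: dict  # case_id -> list of Variant
    haplogroup: dict  # case_id -> name
    content: dict  # case_id -> {"tumor": float, "non_tumor": float}
    ihc_call: dict  # case_id -> positive | negative
    config: SimConfig = None


@dataclass
class SyntheticCohort:
    records: list
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# sequence facet
# ---------------------------------------------------------------------------

def _footprint(v: Variant) -> set[int]:
    return set(range(v.position - 1, v.end + 2))


def _draw_substitution(rng, ref: ReferenceGenome, pos: int, ts_fraction: float) -> str:
    base = ref.base(pos)
    if rng.random() < ts_fraction:
        return TRANSITION_OF[base]
    return TRANSVERSIONS_OF[base][rng.integers(0, 2)]


def _somatic_region_sampler(cfg: SimConfig, ref: ReferenceGenome):
    """Draws a genomic position: control region / MT-ND5 / elsewhere by weight."""
    rmap = ref.region_map
    control = rmap.by_name["MT-DLOOP"]
    nd5 = rmap.by_name["MT-ND5"]
    control_positions = list(range(control.start, MT_LENGTH + 1)) + list(range(1, control.end + 1))
    nd5_positions = list(range(nd5.start, nd5.end + 1))
    excluded = set(control_positions) | set(nd5_positions)
    other_positions = [p for p in range(1, MT_LENGTH + 1) if p not in excluded]
    pools = [control_positions, nd5_positions, other_positions]
    weights = np.array([
        cfg.control_weight, cfg.nd5_weight, 1.0 - cfg.control_weight - cfg.nd5_weight
    ])

    def draw(rng) -> int:
        pool = pools[rng.choice(3, p=weights)]
        return int(pool[rng.integers(0, len(pool))])

    return draw


def _noncoding_positions(ref: ReferenceGenome) -> list[int]:
    coding = set()
    for r in ref.region_map.protein_coding():
        coding.update(range(r.start, r.end + 1))
    return [p for p in range(1, MT_LENGTH + 1) if p not in coding and ref.base(p) != "N"]


def _plant_indel(rng, ref: ReferenceGenome, pos: int, max_len: int = 8) -> Variant:
    length = int(rng.integers(1, max_len + 1))
    if rng.random() < 0.5 and pos + length - 1 <= MT_LENGTH:
        return Variant(pos, ref.slice(pos, pos + length - 1), "", "deletion")
    anchor = ref.base(pos)
    ins = "".join("ACGT"[rng.integers(0, 4)] for _ in range(length))
    return Variant(pos, anchor, anchor + ins, "insertion")


def _generate_case_variants(rng, cfg: SimConfig, ref: ReferenceGenome,
                            table: DiagnosticTable, draw_pos, noncoding: list[int],
                            diagnostic_positions: set[int], haplogroup: str):
    """Germline, somatic and normal-only variant lists for one case."""
    used: set[int] = set()
    germline: list[Variant] = []
    macro, motif = table.motifs[haplogroup]
    for pos, r, a in motif:
        v = Variant(pos, r, a, "substitution")
        germline.append(v)
        used |= _footprint(v)

    n_private = int(rng.poisson(cfg.private_inherited_mean))
    tries = 0
    while n_private > 0 and tries < 500:
        tries += 1
        pos = int(rng.integers(1, MT_LENGTH + 1))
        if pos in diagnostic_positions or ref.base(pos) == "N":
            continue
        v = Variant(pos, ref.base(pos), _draw_substitution(rng, ref, pos, cfg.ts_fraction),
                    "substitution")
        if _footprint(v) & used:
            continue
        germline.append(v)
        used |= _footprint(v)
        n_private -= 1

    if rng.random() < cfg.inherited_indel_rate:
        for _ in range(200):
            pos = noncoding[rng.integers(0, len(noncoding))]
            v = left_normalize(_plant_indel(rng, ref, pos), ref)
            if v.position in diagnostic_positions or _footprint(v) & used:
                continue
            # keep inherited indels strictly outside protein-coding sequence
            span_ok = all(
                all(x.category != "protein_coding" for x in ref.region_map.regions_at(p))
                for p in range(v.position, v.end + 1)
            )
            if not span_ok:
                continue
            germline.append(v)
            used |= _footprint(v)
            break

    somatic: list[Variant] = []
    if rng.random() < cfg.somatic_case_fraction:
        lo, hi = cfg.somatic_per_case
        n_som = int(rng.integers(lo, hi + 1))
        tries = 0
        while len(somatic) < n_som and tries < 500:
            tries += 1
            pos = draw_pos(rng)
            if pos in diagnostic_positions or ref.base(pos) == "N":
                continue
            if rng.random() < cfg.indel_fraction:
                v = left_normalize(_plant_indel(rng, ref, pos, max_len=4), ref)
            else:
                alt = _draw_substitution(rng, ref, pos, cfg.ts_fraction)
                het = bool(rng.random() < cfg.heteroplasmy_rate)
                v = Variant(pos, ref.base(pos), alt, "substitution", heteroplasmic=het)
            if _footprint(v) & used:
                continue
            somatic.append(v)
            used |= _footprint(v)

    normal_only: list[Variant] = []
    if rng.random() < cfg.normal_only_rate:
        for _ in range(200):
            pos = int(rng.integers(1, MT_LENGTH + 1))
            if pos in diagnostic_positions or ref.base(pos) == "N":
                continue
            v = Variant(pos, ref.base(pos), _draw_substitution(rng, ref, pos, cfg.ts_fraction),
                        "substitution", heteroplasmic=True)
            if _footprint(v) & used:
                continue
            normal_only.append(v)
            used |= _footprint(v)
            break

    return germline, somatic, normal_only


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _solve_positivity_intercept(cfg: SimConfig) -> tuple[float, float]:
    """Per-stratum positivity (p_small, p_large) matching marginal rate and OR."""
    from scipy.optimize import brentq

    q = cfg.large_tumor_fraction
    lo_r = math.log(cfg.tfam_size_or)

    def marginal(alpha):
        p_small = 1 / (1 + math.exp(-alpha))
        p_large = 1 / (1 + math.exp(-(alpha + lo_r)))
        return (1 - q) * p_small + q * p_large - cfg.ihc_positivity

    alpha = brentq(marginal, -20, 20)
    return 1 / (1 + math.exp(-alpha)), 1 / (1 + math.exp(-(alpha + lo_r)))


def generate_cohort(
    cfg: SimConfig | None = None,
    ref: ReferenceGenome | None = None,
    table: DiagnosticTable | None = None,
) -> SyntheticCohort:
    """Generate a full paired cohort plus its ground truth (deterministic in seed)."""
    cfg = cfg or SimConfig()
    cfg.validate()
    ref = ref or load_reference()
    table = table or DiagnosticTable.bundled()
    table.validate_against(ref)

    seq_ss, ct_ss, ihc_ss, cov_ss = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_seq = np.random.default_rng(seq_ss)
    rng_ct = np.random.default_rng(ct_ss)
    rng_ihc = np.random.default_rng(ihc_ss)
    rng_cov = np.random.default_rng(cov_ss)

    hgs = sorted(cfg.haplogroup_freqs)
    hg_p = np.array([cfg.haplogroup_freqs[h] for h in hgs], dtype=float)
    hg_p /= hg_p.sum()
    draw_pos = _somatic_region_sampler(cfg, ref)
    noncoding = _noncoding_positions(ref)
    diagnostic_positions = {p for _, sites in table.motifs.values() for p, _, _ in sites}

    sigma = cfg.content_log_sd()
    mu_n = math.log(cfg.non_tumor_mean) - sigma**2 / 2.0
    mu_t = mu_n + math.log(cfg.content_ratio)
    p_small, p_large = _solve_positivity_intercept(cfg)
    grades = sorted(cfg.ed_grade_freqs)
    grade_p = np.array([cfg.ed_grade_freqs[g] for g in grades], dtype=float)
    grade_p /= grade_p.sum()
    # lognormal tumor size with P(size > 5 cm) = large_tumor_fraction
    size_sigma = 0.45
    size_mu = math.log(5.0) - size_sigma * _st.norm.ppf(1 - cfg.large_tumor_fraction)

    records: list[CohortRecord] = []
    truth = SyntheticTruth({}, {}, {}, {}, {}, {}, cfg)
    width = len(str(cfg.n_cases))
    for i in range(cfg.n_cases):
        case = f"HCC{i + 1:0{width}d}"
        hg = hgs[rng_seq.choice(len(hgs), p=hg_p)]
        germline, somatic, normal_only = _generate_case_variants(
            rng_seq, cfg, ref, table, draw_pos, noncoding, diagnostic_positions, hg
        )
        tumor_seq = apply_variants(ref, germline + somatic)
        normal_seq = apply_variants(ref, germline + normal_only)

        content_n = float(math.exp(rng_ct.normal(mu_n, sigma)))
        content_t = float(math.exp(rng_ct.normal(mu_t, sigma)))
        ct_rows = []
        for tissue, content in (("tumor", content_t), ("non_tumor", content_n)):
            base_nuc = float(rng_ct.normal(cfg.ct_nuc_mean, cfg.ct_nuc_sd))
            base_mt = base_nuc - math.log2(content)
            for rep in range(1, cfg.n_replicates + 1):
                ct_rows.append((tissue, "mt", rep, base_mt + float(rng_ct.normal(0, cfg.ct_noise_sd))))
                ct_rows.append((tissue, "nuc", rep, base_nuc + float(rng_ct.normal(0, cfg.ct_noise_sd))))

        size = float(math.exp(rng_cov.normal(size_mu, size_sigma)))
        p_pos = p_large if size > 5.0 else p_small
        positive = bool(rng_ihc.random() < p_pos)
        if positive:
            intensity = int(rng_ihc.choice([1, 2, 3], p=[0.2, 0.4, 0.4]))
            area = int(rng_ihc.choice([1, 2, 3, 4], p=[0.1, 0.2, 0.3, 0.4]))
        else:
            intensity = 0
            area = int(rng_ihc.choice([0, 1], p=[0.7, 0.3]))
        age = float(np.clip(rng_cov.normal(cfg.age_mean, cfg.age_sd), 24, 84))
        gender = "male" if rng_cov.random() < cfg.male_fraction else "female"
        grade = grades[rng_cov.choice(len(grades), p=grade_p)]

        records.append(CohortRecord(
            case_id=case, tumor_seq=tumor_seq, normal_seq=normal_seq, haplogroup=hg,
            ct_rows=ct_rows, intensity=intensity, area_grade=area,
            age=round(age, 1), gender=gender, ed_grade=grade, tumor_size_cm=round(size, 2),
        ))
        truth.germline[case] = germline
        truth.somatic[case] = somatic
        truth.normal_only[case] = normal_only
        truth.haplogroup[case] = hg
        truth.content[case] = {"tumor": content_t, "non_tumor": content_n}
        truth.ihc_call[case] = combine_score(intensity, area).call
    return SyntheticCohort(records=records, truth=truth)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict:
    """Emit all cohort files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "cohort.fa",
        "ct": outdir / "ct_values.tsv",
        "ihc": outdir / "ihc_scores.tsv",
        "covariates": outdir / "covariates.tsv",
        "truth": outdir / "truth.json",
    }
    with open(paths["fasta"], "w") as fh:
        for r in cohort.records:
            for suffix, seq in (("T", r.tumor_seq), ("N", r.normal_seq)):
                fh.write(f">{r.case_id}_{suffix}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
    with open(paths["ct"], "w") as fh:
        fh.write("case\ttissue\ttarget\treplicate\tct\n")
        for r in cohort.records:
            for tissue, target, rep, ct in r.ct_rows:
                fh.write(f"{r.case_id}\t{tissue}\t{target}\t{rep}\t{ct:.4f}\n")
    with open(paths["ihc"], "w") as fh:
        fh.write("case\tintensity\tarea_grade\n")
        for r in cohort.records:
            fh.write(f"{r.case_id}\t{r.intensity}\t{r.area_grade}\n")
    with open(paths["covariates"], "w") as fh:
        fh.write("case\tage\tgender\ted_grade\ttumor_size_cm\n")
        for r in cohort.records:
            fh.write(f"{r.case_id}\t{r.age}\t{r.gender}\t{r.ed_grade}\t{r.tumor_size_cm}\n")
    t = cohort.truth

    def vlist(vs):
        return [
            {"position": v.position, "ref": v.ref_allele, "alt": v.alt_allele,
             "kind": v.kind, "heteroplasmic": v.heteroplasmic}
            for v in vs
        ]

    payload = {
        "haplogroup": t.haplogroup,
        "content": t.content,
        "ihc_call": t.ihc_call,
        "germline": {k: vlist(v) for k, v in t.germline.items()},
        "somatic": {k: vlist(v) for k, v in t.somatic.items()},
        "normal_only": {k: vlist(v) for k, v in t.normal_only.items()},
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(t.config).items()},
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# synthetic species alignment
# ---------------------------------------------------------------------------

SPECIES_17 = (
    "Homo sapiens", "Pan troglodytes", "Pan paniscus", "Gorilla gorilla",
    "Pongo pygmaeus", "Hylobates lar", "Macaca mulatta", "Macaca sylvanus",
    "Cebus albifrons", "Tarsius bancanus", "Lemur catta", "Nycticebus coucang",
    "Mus musculus", "Rattus norvegicus", "Bos taurus", "Gallus gallus",
    "Xenopus laevis",
)


def synthetic_species_alignment(
    ref: ReferenceGenome | None = None,
    seed: int = 0,
    species: tuple = SPECIES_17,
    divergence: tuple = (0.02, 0.35),
    gap_rate: float = 0.005,
) -> SpeciesAlignment:
    """A synthetic vertebrate alignment: human row = rCRS, others mutated copies.

    Stand-in for a real multi-species alignment (which the conservation
    statistic needs but whose provenance is outside this package's scope):
    per-species divergence grows linearly across the list from
    ``divergence[0]`` to ``divergence[1]``, substitutions uniform over the
    three alternates, plus sparse gap columns. Conservation values computed
    from it are internally consistent but not comparable to published
    per-site scores.
    """
    ref = ref or load_reference()
    rng = np.random.default_rng(seed)
    human = ref.sequence
    n = len(species)
    rows = {species[0]: human}
    for i, sp in enumerate(species[1:], start=1):
        d = divergence[0] + (divergence[1] - divergence[0]) * (i - 1) / max(n - 2, 1)
        seq = np.frombuffer(human.encode(), dtype="S1").copy()
        n_mut = rng.binomial(MT_LENGTH, d)
        pos = rng.choice(MT_LENGTH, size=n_mut, replace=False)
        for p in pos:
            base = seq[p].decode()
            if base == "N":
                continue
            alts = [b for b in "ACGT" if b != base]
            seq[p] = alts[rng.integers(0, 3)].encode()
        gaps = rng.random(MT_LENGTH) < gap_rate
        seq[gaps] = b"-"
        rows[sp] = seq.tobytes().decode()
    return SpeciesAlignment(rows=rows, human=species[0])


# ---------------------------------------------------------------------------
# synthetic annotation side-tables
# ---------------------------------------------------------------------------

def synthetic_known_table(cohort: SyntheticCohort, seed: int = 0):
    """A Mitomap-style known-variant table covering most germline variants.

    Germline variants are 'known' with population frequencies above the rare
    threshold; each somatic variant is known-rare with probability 0.65 and
    unreported otherwise (roughly the study's 31/46 reported somatic calls).
    """
    from .scores import KnownVariantTable

    rng = np.random.default_rng(seed)
    freqs = {}
    for case in sorted(cohort.truth.germline):
        for v in cohort.truth.germline[case]:
            key = (v.position, v.ref_allele, v.alt_allele)
            if key not in freqs:
                freqs[key] = float(rng.uniform(0.01, 0.5))
    for case in sorted(cohort.truth.somatic):
        for v in cohort.truth.somatic[case]:
            key = (v.position, v.ref_allele, v.alt_allele)
            if key not in freqs and rng.random() < 0.65:
                freqs[key] = float(rng.uniform(1e-4, 4e-3))
    return KnownVariantTable(freqs)


def synthetic_prediction_panels(variant_keys: list, seed: int = 0,
                                pathogenic_fraction: float = 1.0) -> dict:
    """Six-program verdict panels for nonsynonymous variants.

    With probability ``pathogenic_fraction`` a variant receives 4-6
    deleterious verdicts (a putative pathogenic call under the strict
    majority rule), otherwise 0-3.
    """
    from .scores import DELETERIOUS, TOLERATED, PredictionPanel

    rng = np.random.default_rng(seed)
    programs = ["PolyPhen-2", "SIFT", "MutationAssessor", "Provean", "PANTHER", "TransFIC"]
    panels = {}
    for key in variant_keys:
        n_del = int(rng.integers(4, 7)) if rng.random() < pathogenic_fraction else int(rng.integers(0, 4))
        idx = rng.permutation(6)
        verdicts = {programs[j]: (DELETERIOUS if k < n_del else TOLERATED)
                    for k, j in enumerate(idx)}
        panels[key] = PredictionPanel(verdicts)
    return panels


# ---------------------------------------------------------------------------
# end-to-end recovery
# ---------------------------------------------------------------------------

def end_to_end_recovery(cfg: SimConfig | None = None,
                        ref: ReferenceGenome | None = None) -> dict:
    """Run the full pipeline on a generated cohort and score it against truth.

    Reports somatic/inherited classification accuracy, haplogroup accuracy,
    the copy-number ratio and reduced-fraction estimates, the observed
    somatic case fraction and transition fraction, and the IHC positivity
    and size-association odds ratio.
    """
    from .variants import call_variants, classify_pair, substitution_class
    from .haplogroups import assign
    from .copy_number import CtRecord, cohort_contents, paired_summary
    from .ihc import association_table, combine_score as _combine

    cfg = cfg or SimConfig()
    ref = ref or load_reference()
    table = DiagnosticTable.bundled()
    cohort = generate_cohort(cfg, ref, table)

    som_truth_total = som_called_correct = som_called_total = 0
    hg_correct = 0
    somatic_cases = 0
    ts = tv = 0
    for r in cohort.records:
        t_calls = call_variants(r.tumor_seq, ref, r.case_id, "tumor")
        n_calls = call_variants(r.normal_seq, ref, r.case_id, "non_tumor")
        cs = classify_pair(t_calls, n_calls)
        true_som = {v.key for v in cohort.truth.somatic[r.case_id]}
        called_som = {v.key for v in cs.somatic}
        som_truth_total += len(true_som)
        som_called_total += len(called_som)
        som_called_correct += len(true_som & called_som)
        if called_som:
            somatic_cases += 1
        for v in t_calls + [x for x in n_calls if x.key not in {y.key for y in t_calls}]:
            c = substitution_class(v)
            ts += c == "transition"
            tv += c == "transversion"
        if assign(cs.inherited, table).haplogroup == r.haplogroup:
            hg_correct += 1

    ct_records = []
    for r in cohort.records:
        import pandas as pd

        df = pd.DataFrame(r.ct_rows, columns=["tissue", "target", "replicate", "ct"])
        for tissue, sub in df.groupby("tissue"):
            m = sub.groupby("target")["ct"].mean()
            ct_records.append(CtRecord(r.case_id, tissue, float(m["mt"]), float(m["nuc"])))
    cn = paired_summary(cohort_contents(ct_records))

    calls = [_combine(r.intensity, r.area_grade).call for r in cohort.records]
    large = [r.tumor_size_cm > 5.0 for r in cohort.records]
    assoc = association_table(calls, large)

    n = len(cohort.records)
    return {
        "somatic_recall": som_called_correct / som_truth_total if som_truth_total else 1.0,
        "somatic_precision": som_called_correct / som_called_total if som_called_total else 1.0,
        "somatic_case_fraction": somatic_cases / n,
        "haplogroup_accuracy": hg_correct / n,
        "transition_fraction": ts / (ts + tv) if ts + tv else float("nan"),
        "content_ratio": cn["ratio_of_means"],
        "fraction_reduced": cn["fraction_reduced"],
        "ihc_positivity": sum(c == "positive" for c in calls) / n,
        "ihc_size_odds_ratio": assoc["odds_ratio"],
        "n_cases": n,
    }
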