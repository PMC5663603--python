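"""Simplified Asian mtDNA haplogroup assignment and distribution tests.

Full Phylotree nomenclature is out of scope: assignment works from a flat
diagnostic table giving, for each of 11 coarse haplogroups (D, G, M7, M8, M12
under macro-haplogroup M; A, N9, R9, R11, B, H2 under N), a motif of
rCRS-relative defining substitutions. A case's inherited variants are matched
against every motif and the haplogroup with the highest fraction of defining
positions matched wins; ties break toward the larger absolute match count,
then alphabetically. A case matching no defining variant at all is
"unclassified" rather than an error.

The bundled table (``haplogroup_motifs_synthetic.tsv``) is a constructed
simplified stand-in, not Phylotree: motif positions are plausible diagnostic
sites validated against the bundled rCRS, sufficient for cohort simulation
and recovery testing but not for lineage-accurate typing of real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .reference import _data_path

MACROS = ("M", "N")


class DegenerateTableError(ValueError):
    """Degenerate contingency table (zero margin or too few categories)."""


@dataclass(frozen=True)
class HaplogroupCall:
    haplogroup: str  # one of the table's haplogroups, or "unclassified"
    macro: str  # M | N | "" when unclassified
    n_matched: int
    n_defining: int

    @property
    def fraction(self) -> float:
        return self.n_matched / self.n_defining if self.n_defining else 0.0


class DiagnosticTable:
    """Defining-variant motifs per haplogroup."""

    def __init__(self, motifs: dict[str, tuple[str, list[tuple[int, str, str]]]]):
        if not motifs:
            raise ValueError("empty diagnostic table")
        for hg, (macro, sites) in motifs.items():
            if macro not in MACROS:
                raise ValueError(f"haplogroup {hg} has unknown macro group {macro!r}")
            if not sites:
                raise ValueError(f"haplogroup {hg} has no defining variants")
        self.motifs = motifs

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiagnosticTable":
        df = pd.read_csv(path, sep="\t")
        motifs: dict = {}
        for _, r in df.iterrows():
            hg = str(r["haplogroup"])
            entry = motifs.setdefault(hg, (str(r["macro"]), []))
            if entry[0] != str(r["macro"]):
                raise ValueError(f"haplogroup {hg} maps to two macro groups")
            entry[1].append((int(r["position"]), str(r["ref"]), str(r["alt"])))
        return cls(motifs)

    @classmethod
    def bundled(cls) -> "DiagnosticTable":
        return cls.from_tsv(_data_path("haplogroup_motifs_synthetic.tsv"))

    def validate_against(self, ref) -> None:
        """Check every motif ref allele against a ReferenceGenome."""
        for hg, (_, sites) in self.motifs.items():
            for pos, r, a in sites:
                if ref.base(pos) != r:
                    raise ValueError(
                        f"motif {hg} {pos}{r}>{a} disagrees with reference base {ref.base(pos)}"
                    )

    def macro_of(self, haplogroup: str) -> str:
        return self.motifs[haplogroup][0]


def assign(inherited, table: DiagnosticTable) -> HaplogroupCall:
    """Call the best-supported haplogroup from a case's inherited variants.

    ``inherited`` is a list of Variant objects or (position, ref, alt)
    tuples; only substitutions participate in motif matching. Deterministic:
    invariant to input order, ties broken by (fraction, n_matched,
    alphabetical).
    """
    present = set()
    for v in inherited:
        if isinstance(v, tuple):
            present.add(v)
        elif v.kind == "substitution":
            present.add((v.position, v.ref_allele, v.alt_allele))
    best: HaplogroupCall | None = None
    for hg in sorted(table.motifs):
        macro, sites = table.motifs[hg]
        n_matched = sum(1 for s in sites if s in present)
        call = HaplogroupCall(hg, macro, n_matched, len(sites))
        if best is None or (call.fraction, call.n_matched) > (best.fraction, best.n_matched):
            best = call
    if best is None or best.n_matched == 0:
        return HaplogroupCall("unclassified", "", 0, 0)
    return best


def distribution_test(
    calls: list[HaplogroupCall],
    subset: list[bool] | None = None,
    by: str = "macro",
) -> tuple[float, int, float]:
    """Pearson chi-square test of haplogroup distribution bias.

    With ``subset=None`` this is a goodness-of-fit test of the category
    counts (macro M/N by default, per-haplogroup with ``by='haplogroup'``)
    against a uniform null. With a boolean ``subset`` mask it is a
    2 x k contingency test of subset versus complement, without continuity
    correction. Returns (chi_square, df, P).
    """
    labels = [getattr(c, by) for c in calls if getattr(c, by)]
    cats = sorted(set(labels))
    if len(cats) < 2:
        raise DegenerateTableError("need at least two haplogroup categories with nonzero totals")
    if subset is None:
        counts = [labels.count(c) for c in cats]
        chi2, p = stats.chisquare(counts)
        return float(chi2), len(cats) - 1, float(p)
    if len(subset) != len(calls):
        raise DegenerateTableError("subset mask length must equal the number of calls")
    rows = []
    for flag in (True, False):
        rows.append([
            sum(1 for c, s in zip(calls, subset) if s == flag and getattr(c, by) == cat)
            for cat in cats
        ])
    table = pd.DataFrame(rows, columns=cats).to_numpy()
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError(
            "degenerate contingency table: a row or column margin is zero "
            f"(margins {table.sum(axis=1).tolist()} / {table.sum(axis=0).tolist()})"
        )
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
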