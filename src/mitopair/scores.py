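"""Inter-species conservation and consensus pathogenicity scoring.

Conservation of an rCRS position is the fraction of species in a vertebrate
multiple alignment (human included, 17 rows expected) whose aligned base
equals the human wild-type base; alignment gaps count as non-matching.

Pathogenicity is a majority vote over a panel of six external predictor
programs whose verdicts are supplied as a table: a variant is putative
pathogenic iff strictly more than half of the fixed panel size (i.e. >= 4 of
6) call it deleterious; missing verdicts count as non-deleterious so the rule
stays deterministic.

A frequency filter against a known-variant table (Mitomap-style) classifies
variants as unreported, rare (< 0.5%) or common.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import AlignIO

from .reference import CoordinateError

DELETERIOUS, TOLERATED, MISSING = "deleterious", "tolerated", "missing"
PANEL_SIZE = 6
RARE_FREQUENCY = 0.005


class EvaluationError(ValueError):
    """No usable predictor verdicts for a variant."""


@dataclass
class SpeciesAlignment:
    """A multi-species alignment of the mitochondrial genome.

    ``rows`` maps species name to its aligned sequence (gaps as '-');
    ``human`` names the human row. Column lookup by rCRS position follows the
    human row's ungapped coordinates.
    """

    rows: dict[str, str]
    human: str = "Homo sapiens"
    _col_of: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.human not in self.rows:
            raise ValueError(f"human row {self.human!r} missing from alignment")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        self._col_of = [
            i for i, c in enumerate(self.rows[self.human]) if c != "-"
        ]

    @classmethod
    def from_fasta(cls, path: str | Path, human: str = "Homo sapiens") -> "SpeciesAlignment":
        aln = AlignIO.read(str(path), "fasta")
        rows = {rec.description.split(" ", 1)[-1] if " " in rec.description else rec.id:
                str(rec.seq).upper() for rec in aln}
        key = human if human in rows else next(iter(rows))
        return cls(rows=rows, human=human if human in rows else key)

    @property
    def n_species(self) -> int:
        return len(self.rows)

    def column(self, position: int) -> dict[str, str]:
        """Aligned bases of all species at a 1-based rCRS position."""
        if not 1 <= position <= len(self._col_of):
            raise CoordinateError(
                f"position {position} not aligned in the human row "
                f"(ungapped length {len(self._col_of)})"
            )
        col = self._col_of[position - 1]
        return {sp: seq[col] for sp, seq in self.rows.items()}


def conservation_score(position: int, aln: SpeciesAlignment) -> tuple[int, int, float]:
    """(n_matching, n_total, fraction) of species carrying the human base.

    The human row is itself counted (a fully conserved column in a 17-row
    alignment scores 17/17). Gaps never match.
    """
    col = aln.column(position)
    wild_type = col[aln.human]
    if wild_type == "-":
        raise CoordinateError(f"position {position} is gapped in the human row")
    n_total = aln.n_species
    n_matching = sum(1 for b in col.values() if b == wild_type)
    return n_matching, n_total, n_matching / n_total


@dataclass(frozen=True)
class PredictionPanel:
    """Verdicts of the external predictor programs for one variant."""

    verdicts: dict  # program name -> deleterious | tolerated | missing
    panel_size: int = PANEL_SIZE

    def __post_init__(self):
        bad = set(self.verdicts.values()) - {DELETERIOUS, TOLERATED, MISSING}
        if bad:
            raise ValueError(f"unknown verdicts {sorted(bad)}")

    @property
    def n_deleterious(self) -> int:
        return sum(1 for v in self.verdicts.values() if v == DELETERIOUS)

    @property
    def n_informative(self) -> int:
        return sum(1 for v in self.verdicts.values() if v != MISSING)


def consensus_pathogenicity(panel: PredictionPanel) -> str:
    """'putative_pathogenic' iff a strict majority of the fixed panel is deleterious.

    With the default panel of 6 programs that means at least 4 deleterious
    verdicts; missing verdicts count against, and a panel with no informative
    verdict at all raises :class:`EvaluationError`.
    """
    if panel.n_informative == 0:
        raise EvaluationError("all predictor verdicts missing")
    threshold = panel.panel_size / 2
    return "putative_pathogenic" if panel.n_deleterious > threshold else "not_supported"


def load_prediction_panels(path: str | Path) -> dict[str, PredictionPanel]:
    """Read a predictor TSV (variant, program, verdict) into per-variant panels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"variant", "program", "verdict"}
    if not need <= set(df.columns):
        raise ValueError(f"prediction table needs columns {sorted(need)}")
    panels = {}
    for key, sub in df.groupby("variant"):
        panels[key] = PredictionPanel(dict(zip(sub["program"], sub["verdict"])))
    return panels


class KnownVariantTable:
    """Reported-variant frequencies keyed by (position, ref, alt)."""

    def __init__(self, frequencies: dict):
        for k, f in frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"malformed frequency {f!r} for {k}")
        self.frequencies = dict(frequencies)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KnownVariantTable":
        df = pd.read_csv(path, sep="\t")
        need = {"position", "ref", "alt", "frequency"}
        if not need <= set(df.columns):
            raise ValueError(f"known-variant table needs columns {sorted(need)}")
        freqs = {}
        for _, r in df.iterrows():
            try:
                f = float(r["frequency"])
            except (TypeError, ValueError) as e:
                raise ValueError(f"malformed frequency {r['frequency']!r}") from e
            freqs[(int(r["position"]), str(r["ref"]), str(r["alt"]))] = f
        return cls(freqs)

    def __contains__(self, key) -> bool:
        return key in self.frequencies


def frequency_filter(variant, known: KnownVariantTable) -> str:
    """'unreported', 'rare' (frequency < 0.5%) or 'common'.

    ``variant`` is a :class:`~mitopair.variants.Variant` or a
    (position, ref, alt) tuple.
    """
    key = variant if isinstance(variant, tuple) else (
        variant.position, variant.ref_allele, variant.alt_allele
    )
    if key not in known:
        return "unreported"
    return "rare" if known.frequencies[key] < RARE_FREQUENCY else "common"
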