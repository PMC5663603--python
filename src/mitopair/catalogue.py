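"""Bundled somatic-variant catalogue from a published 86-pair HCC cohort.

``hcc_somatic_catalogue.tsv`` holds the 46 somatic mtDNA variants reported by
an 86-pair hepatocellular carcinoma study (14 control-region substitutions, a
48-bp control-region deletion, control-region insertions, and 25
protein-coding variants including three frameshifts and one nonsense
change), with the published gene assignment, allele notation, reported
status, amino-acid change and inter-species conservation kept verbatim so
the annotation engine can be validated against them.

Two published rows are internally inconsistent with the rCRS and are kept as
printed (the annotator flags rather than forces them): 3877 lists ref T where
the rCRS has G, and 8369 lists alt G with an AA change only a C>T produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .reference import ReferenceGenome, _data_path
from .variants import Variant


@dataclass(frozen=True)
class CatalogueEntry:
    variant: Variant
    gene: str  # published gene/region label
    replacement: str  # published allele notation
    reported: bool  # present in the reported-variant database
    aa_change_printed: str
    conservation_printed: str  # e.g. "16/17", empty when not scored


def load_somatic_catalogue(ref: ReferenceGenome | None = None) -> list[CatalogueEntry]:
    """The 46 catalogued somatic variants as Variant objects plus metadata."""
    df = pd.read_csv(
        _data_path("hcc_somatic_catalogue.tsv"), sep="\t",
        dtype={"position": int, "ref": str, "alt": str}, keep_default_na=False,
    )
    entries = []
    for _, r in df.iterrows():
        kind = r["kind"]
        pos = int(r["position"])
        if kind == "deletion":
            if r["end"]:
                if ref is None:
                    ref = ReferenceGenome.bundled()
                ref_allele = ref.slice(pos, int(r["end"]))
            else:
                ref_allele = r["ref"]
            v = Variant(pos, ref_allele, "", "deletion")
        else:
            v = Variant(pos, r["ref"], r["alt"], kind)
        entries.append(CatalogueEntry(
            variant=v,
            gene=r["gene"],
            replacement=r["replacement"],
            reported=r["reported"] == "Yes",
            aa_change_printed=r["aa_change_printed"],
            conservation_printed=r["conservation_printed"],
        ))
    if len(entries) != 46:
        raise ValueError(f"catalogue must hold 46 variants, found {len(entries)}")
    return entries
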