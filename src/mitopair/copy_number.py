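"""Relative mtDNA copy number from qPCR threshold cycles.

The assay amplifies one mitochondrial target (D-loop) and one single-copy
nuclear target (beta-actin) per sample in triplicate. Relative content is
2^-(Ct_mt - Ct_nuc), assuming 100% amplification efficiency (exponent base
exactly 2; the assay description gives no efficiency correction). Replicates
are combined by the arithmetic mean of Ct before exponentiation.

An optional cohort calibrator rescales every value by one constant (by
default so that the non-tumor mean equals a chosen value); because the
rescaling is a single multiplicative constant, the tumor/non-tumor ratio of
means and the fraction of reduced pairs are calibration-invariant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

TISSUES = ("tumor", "non_tumor")


@dataclass(frozen=True)
class CtRecord:
    """Replicate-averaged threshold cycles for one sample."""

    case_id: str
    tissue: str  # tumor | non_tumor
    ct_mt: float  # D-loop target
    ct_nuc: float  # beta-actin target

    def __post_init__(self):
        for ct in (self.ct_mt, self.ct_nuc):
            if not 0 < ct < 45:
                raise ValueError(f"Ct {ct} outside (0, 45) for {self.case_id}/{self.tissue}")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}")


@dataclass(frozen=True)
class RelativeContent:
    case_id: str
    tissue: str
    value: float  # unitless relative copy number, > 0


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """Load a Ct TSV (case, tissue, target, replicate, ct) and average replicates.

    ``target`` is ``mt`` (D-loop) or ``nuc`` (beta-actin). A sample missing
    either target raises a ValueError.
    """
    df = pd.read_csv(path, sep="\t")
    need = {"case", "tissue", "target", "replicate", "ct"}
    if not need <= set(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(need)}")
    records = []
    for (case, tissue), sub in df.groupby(["case", "tissue"], sort=True):
        means = sub.groupby("target")["ct"].mean()
        if "mt" not in means or "nuc" not in means:
            raise ValueError(f"sample {case}/{tissue} is missing a qPCR target")
        records.append(CtRecord(str(case), str(tissue), float(means["mt"]), float(means["nuc"])))
    return records


def relative_content(rec: CtRecord, calibrator: float = 1.0) -> RelativeContent:
    """2^-(Ct_mt - Ct_nuc), optionally divided by a cohort calibrator constant."""
    if calibrator <= 0:
        raise ValueError("calibrator must be positive")
    value = 2.0 ** (-(rec.ct_mt - rec.ct_nuc)) / calibrator
    return RelativeContent(rec.case_id, rec.tissue, value)


def cohort_contents(
    records: list[CtRecord], calibrate_non_tumor_mean: float | None = None
) -> list[RelativeContent]:
    """Relative contents for a cohort, optionally calibrated.

    With ``calibrate_non_tumor_mean`` set, all values are rescaled by the one
    constant that brings the non-tumor mean to that value (a common choice is
    1.0; the study scale has it near 1.45).
    """
    raw = [relative_content(r) for r in records]
    if calibrate_non_tumor_mean is None:
        return raw
    normals = [c.value for c in raw if c.tissue == "non_tumor"]
    if not normals:
        raise ValueError("cannot calibrate: no non-tumor samples")
    k = float(np.mean(normals)) / calibrate_non_tumor_mean
    return [RelativeContent(c.case_id, c.tissue, c.value / k) for c in raw]


def paired_summary(contents: list[RelativeContent]) -> dict:
    """Tumor/non-tumor comparison over complete pairs.

    Returns group means and SEMs, the ratio of group means, the fraction of
    cases whose tumor value is below the non-tumor value, and the two-sided
    paired t-test P on per-case differences. Unpaired records are excluded
    with a logged warning.
    """
    by_case: dict[str, dict[str, float]] = {}
    for c in contents:
        by_case.setdefault(c.case_id, {})[c.tissue] = c.value
    pairs = {k: v for k, v in by_case.items() if set(v) == set(TISSUES)}
    dropped = sorted(set(by_case) - set(pairs))
    if dropped:
        log.warning("excluding %d unpaired cases: %s", len(dropped), dropped[:10])
    if len(pairs) < 2:
        raise ValueError("need at least 2 complete tumor/non-tumor pairs")
    t = np.array([v["tumor"] for v in pairs.values()])
    n = np.array([v["non_tumor"] for v in pairs.values()])
    if np.allclose(t, n):
        p_value = 1.0
    else:
        p_value = float(stats.ttest_rel(t, n).pvalue)
    sem = lambda x: float(np.std(x, ddof=1) / math.sqrt(len(x)))
    return {
        "n_pairs": len(pairs),
        "mean_T": float(t.mean()),
        "sem_T": sem(t),
        "mean_N": float(n.mean()),
        "sem_N": sem(n),
        "ratio_of_means": float(t.mean() / n.mean()),
        "fraction_reduced": float((t < n).mean()),
        "paired_t_P": p_value,
    }


def plot_paired_contents(contents: list[RelativeContent], path: str | Path) -> None:
    """Column scatter of tumor vs non-tumor relative contents (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = [c.value for c in contents if c.tissue == "tumor"]
    n = [c.value for c in contents if c.tissue == "non_tumor"]
    rng = np.random.default_rng(0)
    fig, ax = plt.subplots(figsize=(3.5, 4))
    for i, (vals, label) in enumerate([(t, "T"), (n, "N")]):
        x = i + rng.uniform(-0.12, 0.12, size=len(vals))
        ax.plot(x, vals, "o", ms=3, alpha=0.6)
        ax.hlines(np.mean(vals), i - 0.2, i + 0.2, color="k")
    ax.set_xticks([0, 1], ["T", "N"])
    ax.set_ylabel("relative mtDNA content")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
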