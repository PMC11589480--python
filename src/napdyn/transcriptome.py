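"""Expression-table filters and regulation-set classification.

Differential-expression statistics themselves come from an upstream DESeq2
run; this module applies the downstream rules to its output schema:

====================  =======================================
rule                  boundary (strict)
====================  =======================================
count filter          genes with total read count < 45 excluded
differential          |log2FC| > 1  AND  padj < 0.05
====================  =======================================

plus two-contrast concordance (same-sign vs opposite-sign regulation) and
the standard TPM transform.  All operations are pure, order-stable set
computations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RegulationSets", "filter_low_counts", "classify_de",
           "concordance", "compute_tpm",
           "COUNT_THRESHOLD", "LFC_THRESHOLD", "PADJ_THRESHOLD"]

COUNT_THRESHOLD = 45    # total read count below this is excluded
LFC_THRESHOLD = 1.0     # |log2FC| must strictly exceed this
PADJ_THRESHOLD = 0.05   # padj must be strictly below this


@dataclass(frozen=True)
class RegulationSets:
    """Up/down gene sets for one contrast, plus cross-contrast overlaps."""

    up: frozenset[str]
    down: frozenset[str]
    common_up: frozenset[str] = frozenset()
    common_down: frozenset[str] = frozenset()
    opposite: frozenset[str] = frozenset()
    pairs: pd.DataFrame | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and downregulated in one contrast")
        if self.opposite & (self.common_up | self.common_down):
            raise ValueError("opposite and common sets must be disjoint")

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)


def filter_low_counts(table: pd.DataFrame, threshold: int = COUNT_THRESHOLD
                      ) -> tuple[pd.DataFrame, int]:
    """Drop genes whose total read count is below the threshold.

    Returns the filtered table and the number of genes removed.  Idempotent.
    """
    keep = table["total_count"] >= threshold
    return table[keep].reset_index(drop=True), int((~keep).sum())


def classify_de(table: pd.DataFrame) -> RegulationSets:
    """Classify one contrast: up if log2fc > 1 and padj < 0.05; down mirrored.

    Inequalities are strict on both thresholds (log2fc exactly 1.0 is not
    differential).  Genes with missing padj are excluded with a warning.
    """
    df = table
    missing = df["padj"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} genes with missing padj excluded "
                      "from DE classification", stacklevel=2)
        df = df[~missing]
    sig = df["padj"] < PADJ_THRESHOLD
    up = frozenset(df.loc[sig & (df["log2fc"] > LFC_THRESHOLD), "gene_id"])
    down = frozenset(df.loc[sig & (df["log2fc"] < -LFC_THRESHOLD), "gene_id"])
    return RegulationSets(up=up, down=down)


def concordance(table_a: pd.DataFrame, table_b: pd.DataFrame) -> RegulationSets:
    """Compare regulation across two contrasts on the shared gene universe.

    common = differential in both with the same sign; opposite =
    differential in both with opposite signs.  The returned ``pairs`` frame
    carries per-gene (log2fc_a, log2fc_b, classification) for every gene
    differential in either contrast, ready for plotting.
    """
    shared = set(table_a["gene_id"]) & set(table_b["gene_id"])
    if not shared:
        warnings.warn("contrasts share no genes; empty concordance", stacklevel=2)
        empty = frozenset()
        return RegulationSets(up=empty, down=empty,
                              pairs=pd.DataFrame(columns=["gene_id", "log2fc_a",
                                                          "log2fc_b", "classification"]))
    a = table_a[table_a["gene_id"].isin(shared)]
    b = table_b[table_b["gene_id"].isin(shared)]
    sets_a, sets_b = classify_de(a), classify_de(b)

    common_up = sets_a.up & sets_b.up
    common_down = sets_a.down & sets_b.down
    opposite = (sets_a.up & sets_b.down) | (sets_a.down & sets_b.up)

    any_de = sorted((sets_a.up | sets_a.down | sets_b.up | sets_b.down))
    fa = a.set_index("gene_id")["log2fc"]
    fb = b.set_index("gene_id")["log2fc"]

    def _cls(g: str) -> str:
        if g in common_up or g in common_down:
            return "common"
        if g in opposite:
            return "opposite"
        return "single"

    pairs = pd.DataFrame({"gene_id": any_de,
                          "log2fc_a": [fa.get(g, np.nan) for g in any_de],
                          "log2fc_b": [fb.get(g, np.nan) for g in any_de],
                          "classification": [_cls(g) for g in any_de]})
    return RegulationSets(up=sets_a.up, down=sets_a.down,
                          common_up=frozenset(common_up),
                          common_down=frozenset(common_down),
                          opposite=frozenset(opposite), pairs=pairs)


def compute_tpm(counts, gene_lengths) -> np.ndarray:
    """Transcripts per million from raw counts and gene lengths (bp).

    tpm_g = 1e6 * (count_g / length_g) / sum_j (count_j / length_j).
    """
    c = np.asarray(counts, dtype=float)
    L = np.asarray(gene_lengths, dtype=float)
    if np.any(L <= 0):
        raise ValueError("gene lengths must be > 0")
    rate = c / L
    total = rate.sum()
    if total == 0:
        raise ValueError("zero library: no reads in any gene")
    return 1e6 * rate / total
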