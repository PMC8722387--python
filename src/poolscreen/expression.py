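"""Coverage-based expression comparison between mutant and sibling pools.

Per-gene mean read depth is normalised to reads-per-million within each
pool, a pseudo-count stabilises low-coverage genes, and genes are ranked by
the log2 mutant/sibling ratio. This is a ranking, not a test: no dispersion
model and no significance calls, matching a screen that asks only "which
transcriptional programs collapsed in the mutants?".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's coverage in both pools, normalised, with the log ratio."""

    gene_id: str
    mut_coverage: float
    sib_coverage: float
    mut_norm: float
    sib_norm: float
    log2_ratio: float


def coverage_table(
    depths: pd.DataFrame,
    pseudo_count: float = 1.0,
    scale: float = 1e6,
    length_normalize: bool = False,
) -> list[ExpressionRecord]:
    """Build expression records from a per-gene depth table.

    ``depths`` needs columns ``gene_id``, ``mut_depth``, ``sib_depth`` (and
    ``length`` when ``length_normalize`` is on, dividing depth by gene
    length before the per-million scaling). Each pool is normalised so its
    coverages sum to ``scale``; the log ratio is
    ``log2((mut_norm + pc) / (sib_norm + pc))``, finite for any
    ``pseudo_count > 0``.
    """
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be > 0")
    required = {"gene_id", "mut_depth", "sib_depth"}
    missing = required - set(depths.columns)
    if missing:
        raise ValueError(f"depth table missing columns {sorted(missing)}")
    if depths["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in depth table")
    mut = depths["mut_depth"].astype(float).to_numpy()
    sib = depths["sib_depth"].astype(float).to_numpy()
    if (mut < 0).any() or (sib < 0).any():
        raise ValueError("depths must be non-negative")
    if length_normalize:
        if "length" not in depths.columns:
            raise ValueError("length_normalize requires a 'length' column")
        length = depths["length"].astype(float).to_numpy()
        if (length <= 0).any():
            raise ValueError("gene lengths must be > 0")
        mut = mut / length
        sib = sib / length
    mut_sum, sib_sum = mut.sum(), sib.sum()
    if mut_sum == 0 or sib_sum == 0:
        raise ValueError("cannot normalize a pool with zero total coverage")
    mut_norm = mut / mut_sum * scale
    sib_norm = sib / sib_sum * scale
    records = []
    for gene_id, mc, sc, mn, sn in zip(
        depths["gene_id"], mut, sib, mut_norm, sib_norm
    ):
        records.append(
            ExpressionRecord(
                gene_id=str(gene_id),
                mut_coverage=float(mc),
                sib_coverage=float(sc),
                mut_norm=float(mn),
                sib_norm=float(sn),
                log2_ratio=math.log2((mn + pseudo_count) / (sn + pseudo_count)),
            )
        )
    return records


def top_downregulated(
    records: Sequence[ExpressionRecord], n: int
) -> list[ExpressionRecord]:
    """The ``n`` most-negative log-ratio genes, most downregulated first.

    Ties break by gene id lexicographically so the ranking is deterministic
    and permutation-invariant.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    ranked = sorted(records, key=lambda r: (r.log2_ratio, r.gene_id))
    return ranked[:n]


def read_depth_table(path: str | Path) -> pd.DataFrame:
    """Read the per-gene depth TSV (gene_id, mut_depth, sib_depth[, length])."""
    return pd.read_csv(path, sep="\t")


def write_ranked_table(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write(
            "rank\tgene_id\tmut_coverage\tsib_coverage\tmut_norm\tsib_norm\tlog2_ratio\n"
        )
        for rank, r in enumerate(records, start=1):
            handle.write(
                f"{rank}\t{r.gene_id}\t{r.mut_coverage:.6g}\t{r.sib_coverage:.6g}"
                f"\t{r.mut_norm:.6g}\t{r.sib_norm:.6g}\t{r.log2_ratio:.6f}\n"
            )
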