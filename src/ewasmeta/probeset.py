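"""Analysis probe-set assembly and nearest-gene annotation.

The analysis set is the intersection of the QC-passing probes of the two
array panels, minus probes on the cell-type-associated exclusion list and
minus cross-reactive (multi-mapping) probes. Exclusion lists are applied
as sets; any overlap between the two lists is counted once and reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "assemble_analysis_set",
    "nearest_gene",
    "read_annotation",
    "read_probe_list",
    "AssemblyBookkeeping",
]


class EmptyProbeSetError(ValueError):
    """All probes excluded: no analysis set remains."""


@dataclass
class AssemblyBookkeeping:
    n_pass_small: int
    n_pass_large: int
    n_common: int
    n_celltype_excluded: int
    n_crossreactive_excluded: int
    n_overlap_between_lists: int
    n_final: int


def assemble_analysis_set(
    ann: pd.DataFrame,
    qc_pass_small,
    qc_pass_large,
    celltype_list=None,
    crossreactive_list=None,
) -> tuple[set, AssemblyBookkeeping]:
    """Intersect panels and subtract the two exclusion lists.

    ``celltype_list`` / ``crossreactive_list`` default to the annotation
    flags ``celltype_associated`` / ``cross_reactive``. Returns the final
    probe id set and subtraction bookkeeping; exclusions are counted
    within the intersection, with any overlap between the two lists
    counted once.
    """
    small, large = set(qc_pass_small), set(qc_pass_large)
    common = small & large
    if celltype_list is None:
        celltype_list = set(ann.index[ann["celltype_associated"].astype(bool)])
    if crossreactive_list is None:
        crossreactive_list = set(ann.index[ann["cross_reactive"].astype(bool)])
    ct = common & set(celltype_list)
    xr = common & set(crossreactive_list)
    final = common - ct - xr
    if not final:
        raise EmptyProbeSetError("no probes remain after exclusions")
    book = AssemblyBookkeeping(
        n_pass_small=len(small),
        n_pass_large=len(large),
        n_common=len(common),
        n_celltype_excluded=len(ct),
        n_crossreactive_excluded=len(xr),
        n_overlap_between_lists=len(ct & xr),
        n_final=len(final),
    )
    assert book.n_common - len(ct | xr) == book.n_final
    return final, book


def nearest_gene(ann: pd.DataFrame, chromosome: str, position: int):
    """Nearest gene to a genomic position (1-based inclusive intervals).

    Distance is 0 inside the gene interval, otherwise the bp gap to the
    nearest interval end; ties break toward the gene with the smaller
    start coordinate. Returns ``(gene, distance)`` or ``(None, None)``
    when the chromosome carries no annotated gene.
    """
    sub = ann[ann["chromosome"].astype(str) == str(chromosome)]
    sub = sub.dropna(subset=["gene_start", "gene_end"])
    if sub.empty:
        return None, None
    start = sub["gene_start"].to_numpy(dtype=float)
    end = sub["gene_end"].to_numpy(dtype=float)
    dist = np.where(
        (position >= start) & (position <= end),
        0.0,
        np.minimum(np.abs(position - start), np.abs(position - end)),
    )
    order = np.lexsort((start, dist))
    best = order[0]
    return sub["nearest_gene"].iloc[best], int(dist[best])


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return ann.set_index("probe_id")


def read_probe_list(path) -> set:
    """One probe id per line; blank lines ignored."""
    return {ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()}
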