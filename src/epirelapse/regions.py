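"""DMR construction and TSS-window gene assignment.

A differentially methylated region (DMR) is a maximal run of neighboring
same-direction DMCs on one chromosome with inter-site gaps no larger than
``max_gap`` and at least ``min_dmcs`` members.  Defaults (gap 300 bp,
3 sites) produce promoter-scale regions; both are exposed on the CLI.

Gene assignment associates a DMR with every gene whose transcription start
site lies within ``window`` bp of the region (the window is applied on both
sides of the TSS, strand-agnostically; strand is carried through for
interpretation only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import natural_chrom_key

DMR_COLUMNS = ["chrom", "start", "end", "direction", "n_dmcs", "mean_delta", "sites"]


def merge_dmrs(
    dmcs: pd.DataFrame, max_gap: int = 300, min_dmcs: int = 3
) -> pd.DataFrame:
    """Merge sorted DMCs into DMRs.

    ``dmcs`` needs columns ``chrom, start, direction, delta`` and must be
    sorted by (chrom, start) in natural chromosome order; runs are broken at
    chromosome or direction changes and at start-to-start gaps > ``max_gap``.
    The region envelope is ``[first start, last start + 2)``.
    """
    if dmcs.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)

    chrom = dmcs["chrom"].to_numpy()
    start = dmcs["start"].to_numpy()
    direction = dmcs["direction"].to_numpy()

    keys = [natural_chrom_key(c) for c in chrom]
    for i in range(1, len(dmcs)):
        if keys[i] < keys[i - 1] or (keys[i] == keys[i - 1] and start[i] < start[i - 1]):
            raise ValidationError("DMC input must be sorted by (chrom, start)")

    same = np.empty(len(dmcs), dtype=bool)
    same[0] = False
    same[1:] = (
        (chrom[1:] == chrom[:-1])
        & (direction[1:] == direction[:-1])
        & (start[1:] - start[:-1] <= max_gap)
    )
    run_id = np.cumsum(~same)

    df = dmcs.assign(_run=run_id)
    rows = []
    for _, grp in df.groupby("_run", sort=True):
        if len(grp) < min_dmcs:
            continue
        rows.append(
            {
                "chrom": grp["chrom"].iloc[0],
                "start": int(grp["start"].iloc[0]),
                "end": int(grp["start"].iloc[-1]) + 2,
                "direction": grp["direction"].iloc[0],
                "n_dmcs": len(grp),
                "mean_delta": float(grp["delta"].mean()),
                "sites": list(zip(grp["chrom"], grp["start"])),
            }
        )
    return pd.DataFrame(rows, columns=DMR_COLUMNS)


def assign_genes(
    dmrs: pd.DataFrame, genes: pd.DataFrame, window: int = 5000
) -> pd.DataFrame:
    """Associate DMRs with genes whose TSS is within ``window`` bp.

    A DMR ``[start, end)`` is associated with a gene iff it overlaps the
    closed interval ``[tss - window, tss + window]``.  ``distance`` is the
    signed offset from the TSS to the nearest covered base of the DMR
    (negative when the DMR lies upstream of the TSS in reference
    coordinates, 0 when the DMR covers the TSS).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    out_rows = []
    if dmrs.empty or genes.empty:
        return pd.DataFrame(
            columns=["chrom", "dmr_start", "dmr_end", "direction", "gene_id", "distance"]
        )
    for chrom, gsub in genes.groupby("chrom", sort=False):
        dsub = dmrs[dmrs["chrom"] == chrom]
        if dsub.empty:
            continue
        gsub = gsub.sort_values("tss")
        tss = gsub["tss"].to_numpy()
        ids = gsub["gene_id"].to_numpy()
        strands = gsub["strand"].to_numpy() if "strand" in gsub else np.full(len(gsub), "+")
        for row in dsub.itertuples(index=False):
            # genes with tss in [start - window, end - 1 + window]
            lo = np.searchsorted(tss, row.start - window, side="left")
            hi = np.searchsorted(tss, row.end - 1 + window, side="right")
            for j in range(lo, hi):
                t = int(tss[j])
                if row.start <= t < row.end:
                    dist = 0
                elif row.end <= t:
                    dist = (row.end - 1) - t  # DMR upstream of TSS: negative
                else:
                    dist = row.start - t  # DMR downstream of TSS: positive
                out_rows.append(
                    {
                        "chrom": chrom,
                        "dmr_start": int(row.start),
                        "dmr_end": int(row.end),
                        "direction": getattr(row, "direction", ""),
                        "gene_id": ids[j],
                        "distance": dist,
                        "strand": strands[j],
                    }
                )
    return pd.DataFrame(
        out_rows,
        columns=["chrom", "dmr_start", "dmr_end", "direction", "gene_id", "distance", "strand"],
    )


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """BED6+ view of a DMR table (name=direction, score=1000*|mean_delta|)."""
    return pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"],
            "end": dmrs["end"],
            "name": dmrs["direction"],
            "score": (1000 * dmrs["mean_delta"].abs()).round().astype(int),
            "strand": ".",
            "n_dmcs": dmrs["n_dmcs"],
            "mean_delta": dmrs["mean_delta"],
        }
    )
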