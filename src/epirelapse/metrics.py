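"""Cohort-level descriptive metrics.

* **Convergence series** — Pearson correlation of methylation ratios between
  consecutively relapsing tumors of one patient; when the adjacent previous
  relapse is missing, the nearest earlier available sample is used instead
  (flagged ``fallback_used``).  In serially relapsing tumors this series
  rises with relapse number: the methylome converges.
* **PDOX fidelity** — global Pearson r between a patient sample and its
  matched orthotopic xenograft over shared covered CpGs.
* **Top-variable CpG selection** — the k complete-case sites with largest
  across-sample ratio variance (heatmap/phylogeny input).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyComparisonError, EmptySelectionError, ValidationError
from .io import natural_chrom_key

CONVERGENCE_COLUMNS = [
    "earlier",
    "later",
    "timepoint",
    "pearson_r",
    "n_shared_sites",
    "fallback_used",
    "low_site_warning",
]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson needs two equal-length 1-D vectors")
    return float(np.corrcoef(x, y)[0, 1])


def _shared_ratios(
    a: pd.DataFrame, b: pd.DataFrame, min_reads: int
) -> tuple[np.ndarray, np.ndarray]:
    a = a[a["total_reads"] >= min_reads]
    b = b[b["total_reads"] >= min_reads]
    merged = a.merge(b, on=["chrom", "start"], suffixes=("_a", "_b"), how="inner")
    return merged["ratio_a"].to_numpy(), merged["ratio_b"].to_numpy()


def convergence_series(
    samples: Sequence[tuple[str, int, pd.DataFrame]],
    min_reads: int = 5,
    min_shared: int = 100,
) -> pd.DataFrame:
    """Consecutive-relapse correlation records for one patient.

    ``samples`` holds ``(sample_id, timepoint, methylation table)`` for the
    patient's available tumor samples, ordered by timepoint (primary = 0).
    Each later sample is correlated with the nearest earlier available one;
    ``fallback_used`` marks pairs whose timepoints are not adjacent.
    """
    if len(samples) < 2:
        raise ValidationError("convergence needs >= 2 tumor samples")
    timepoints = [t for _, t, _ in samples]
    if timepoints != sorted(timepoints):
        raise ValidationError("samples must be ordered by timepoint")

    rows = []
    for (id_a, t_a, df_a), (id_b, t_b, df_b) in zip(samples, samples[1:]):
        x, y = _shared_ratios(df_a, df_b, min_reads)
        if len(x) == 0:
            raise EmptyComparisonError(f"{id_a} and {id_b} share no covered sites")
        rows.append(
            {
                "earlier": id_a,
                "later": id_b,
                "timepoint": t_b,
                "pearson_r": pearson(x, y),
                "n_shared_sites": len(x),
                "fallback_used": t_b - t_a != 1,
                "low_site_warning": len(x) < min_shared,
            }
        )
    return pd.DataFrame(rows, columns=CONVERGENCE_COLUMNS)


def global_fidelity(
    patient: pd.DataFrame, pdox: pd.DataFrame, min_reads: int = 5
) -> tuple[float, int]:
    """Pearson r between a patient sample and its matched PDOX model."""
    x, y = _shared_ratios(patient, pdox, min_reads)
    if len(x) == 0:
        raise EmptyComparisonError("patient and PDOX share no covered sites")
    return pearson(x, y), len(x)


def top_variable_cpgs(ratios: pd.DataFrame, k: int) -> pd.DataFrame:
    """Select the k most variable complete-case sites.

    ``ratios`` is a sites x samples frame indexed by (chrom, start); only
    sites covered in every sample (no NaN) are eligible.  Ties are broken by
    natural (chrom, start) order.
    """
    eligible = ratios.dropna(axis=0, how="any")
    if k > len(eligible):
        raise EmptySelectionError(
            f"k={k} exceeds the {len(eligible)} sites covered in all samples"
        )
    var = eligible.var(axis=1, ddof=1)
    order = sorted(
        range(len(eligible)),
        key=lambda i: (
            -var.iloc[i],
            natural_chrom_key(eligible.index[i][0]),
            eligible.index[i][1],
        ),
    )
    return eligible.iloc[order[:k]]


def distance_matrix(ratios: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson r between all sample pairs (complete-case sites)."""
    complete = ratios.dropna(axis=0, how="any")
    if complete.empty:
        raise EmptySelectionError("no sites covered in all samples")
    corr = np.corrcoef(complete.to_numpy().T)
    return pd.DataFrame(1.0 - corr, index=ratios.columns, columns=ratios.columns)
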