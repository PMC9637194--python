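"""Per-site differential methylation calling (tumor vs matched normal).

A differentially methylated cytosine (DMC) is a single CpG whose
methylated/unmethylated read counts differ between a tumor sample and its
matched normal tissue.  The caller is deliberately transparent:

* two-sided Fisher exact test on the 2x2 table
  ``[(meth, unmeth)_tumor; (meth, unmeth)_normal]``,
* Benjamini-Hochberg FDR across all sites tested in the comparison,
* a minimum methylation-ratio difference ``|delta| >= delta_min``.

A site is ``Hyper`` when ``delta >= +delta_min`` and ``q <= q_max``,
``Hypo`` symmetrically, otherwise ``NoChange``.  Sites failing the coverage
filter in either sample are never tested (no imputation).

The Fisher p-values are computed by exhaustive enumeration over the
hypergeometric support, vectorised over unique tables so that cohort-scale
inputs (millions of tests) stay fast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import EmptyComparisonError, EmptySelectionError
from . import io as eio

#: relative tolerance when deciding which enumerated tables are "at least as
#: extreme" as the observed one (guards against floating-point ties; matches
#: the convention of the classical two-sided Fisher test)
_TIE_REL_TOL = 1e-7

DMC_COLUMNS = [
    "chrom",
    "start",
    "end",
    "delta",
    "direction",
    "p_value",
    "q_value",
    "tumor_cov",
    "normal_cov",
]


def filter_coverage(records: pd.DataFrame, min_reads: int = 5) -> pd.DataFrame:
    """Retain sites with ``total_reads >= min_reads`` (order preserved).

    The default mirrors the standard RRBS practice of using only CpG sites
    covered by five or more reads.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return records.loc[records["total_reads"] >= min_reads].reset_index(drop=True)


def fisher_exact_two_sided(
    meth_a: np.ndarray, unmeth_a: np.ndarray, meth_b: np.ndarray, unmeth_b: np.ndarray
) -> np.ndarray:
    """Vectorised two-sided Fisher exact p for many 2x2 tables.

    For each table the p-value is the sum of hypergeometric point
    probabilities over all tables with the observed margins whose probability
    does not exceed that of the observed table (with a small relative
    tolerance for ties).
    """
    a = np.asarray(meth_a, dtype=np.int64)
    b = np.asarray(unmeth_a, dtype=np.int64)
    c = np.asarray(meth_b, dtype=np.int64)
    d = np.asarray(unmeth_b, dtype=np.int64)
    if a.shape != b.shape or a.shape != c.shape or a.shape != d.shape:
        raise ValueError("count arrays must share a shape")
    tables = np.stack([a, b, c, d], axis=1)
    uniq, inverse = np.unique(tables, axis=0, return_inverse=True)
    p_uniq = np.empty(len(uniq))
    chunk = 20_000
    for lo in range(0, len(uniq), chunk):
        block = uniq[lo : lo + chunk]
        p_uniq[lo : lo + chunk] = _fisher_block(block)
    return p_uniq[inverse]


def _fisher_block(tables: np.ndarray) -> np.ndarray:
    a, b, c, d = (tables[:, i] for i in range(4))
    draws = a + b            # tumor row margin
    successes = a + c        # methylated column margin
    total = a + b + c + d
    k_min = np.maximum(0, successes - (c + d))
    k_max = np.minimum(successes, draws)
    width = int((k_max - k_min).max()) + 1 if len(tables) else 0
    k = k_min[:, None] + np.arange(width)[None, :]
    valid = k <= k_max[:, None]
    pmf = hypergeom.pmf(np.where(valid, k, 0), total[:, None], successes[:, None], draws[:, None])
    p_obs = hypergeom.pmf(a, total, successes, draws)
    take = valid & (pmf <= p_obs[:, None] * (1.0 + _TIE_REL_TOL))
    p = np.where(take, pmf, 0.0).sum(axis=1)
    return np.minimum(p, 1.0)


def call_dmcs(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    delta_min: float = 0.2,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Call DMCs between one tumor sample and its matched normal.

    Both inputs are coverage-filtered methylation tables; sites are matched
    on (chrom, start) and unmatched sites dropped.  Returns a frame with
    :data:`DMC_COLUMNS`, sorted by (chrom, start).
    """
    merged = tumor.merge(
        normal, on=["chrom", "start"], suffixes=("_t", "_n"), how="inner"
    )
    if merged.empty:
        raise EmptyComparisonError("tumor and normal share no covered sites")

    meth_t = merged["meth_reads_t"].to_numpy()
    tot_t = merged["total_reads_t"].to_numpy()
    meth_n = merged["meth_reads_n"].to_numpy()
    tot_n = merged["total_reads_n"].to_numpy()

    delta = meth_t / tot_t - meth_n / tot_n
    p = fisher_exact_two_sided(meth_t, tot_t - meth_t, meth_n, tot_n - meth_n)
    q = multipletests(p, method="fdr_bh")[1]

    significant = q <= q_max
    direction = np.where(
        significant & (delta >= delta_min),
        "Hyper",
        np.where(significant & (delta <= -delta_min), "Hypo", "NoChange"),
    )

    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "start": merged["start"],
            "end": merged["start"] + 2,
            "delta": delta,
            "direction": direction,
            "p_value": p,
            "q_value": q,
            "tumor_cov": tot_t,
            "normal_cov": tot_n,
        }
    )
    return eio.sort_sites(out)


def summarize_context(records: pd.DataFrame, context: str) -> float:
    """Arithmetic mean methylation ratio over sites of one sequence context.

    Used for the global mCpA comparison between tumors and normal brain
    tissue; the input should already be coverage-filtered.
    """
    sel = records.loc[records["context"] == context, "ratio"]
    if sel.empty:
        raise EmptySelectionError(f"no sites with context {context!r}")
    return float(sel.mean())
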