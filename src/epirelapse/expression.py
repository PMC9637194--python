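"""Differential expression and methylation-expression integration.

Expression is normalized to counts-per-million (CPM) on library size; genes
are tested tumor vs normal with a two-sided Welch t-test on log2(CPM+1) and
Benjamini-Hochberg adjusted.  A gene is a DEG at ``q <= 0.05`` and
``|log2 fold change| >= 1`` (fold change of 2 or more, boundary inclusive).

Integration asks whether a candidate DMR-associated gene behaves like a
methylation-regulated gene: the DMR's mean methylation across samples must
anticorrelate with the gene's expression (Pearson r < 0), and the DEG
polarity must be concordant with the DMR polarity (hypermethylated promoter
-> downregulated gene, hypomethylated -> upregulated).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEG_COLUMNS = [
    "gene_id",
    "log2_fold_change",
    "p_value",
    "q_value",
    "mean_expr_tumor",
    "mean_expr_normal",
    "is_deg",
]


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million on library size (column sums)."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    return counts * 1e6 / lib


def call_degs(
    counts: pd.DataFrame,
    tumor_samples: list[str],
    normal_samples: list[str],
    q_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Two-group DEG calling on a genes x samples count matrix."""
    if len(tumor_samples) < 2 or len(normal_samples) < 2:
        raise ValueError("need >= 2 samples per group")
    used = counts[tumor_samples + normal_samples]
    if (used < 0).any().any():
        raise ValueError("counts must be nonnegative")
    used = used.loc[used.sum(axis=1) > 0]  # all-zero genes are untestable

    norm = cpm(used)
    log_expr = np.log2(norm + 1.0)
    t_log = log_expr[tumor_samples].to_numpy()
    n_log = log_expr[normal_samples].to_numpy()

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(t_log, n_log, axis=1, equal_var=False)
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        mean_t = norm[tumor_samples].mean(axis=1).to_numpy()
        mean_n = norm[normal_samples].mean(axis=1).to_numpy()
        log2fc = np.log2(mean_t / mean_n)

    q = multipletests(p, method="fdr_bh")[1]
    is_deg = (q <= q_max) & (np.abs(log2fc) >= min_abs_log2fc)

    return pd.DataFrame(
        {
            "gene_id": used.index,
            "log2_fold_change": log2fc,
            "p_value": p,
            "q_value": q,
            "mean_expr_tumor": log_expr[tumor_samples].mean(axis=1).to_numpy(),
            "mean_expr_normal": log_expr[normal_samples].mean(axis=1).to_numpy(),
            "is_deg": is_deg,
        }
    ).reset_index(drop=True)


def integrate(
    candidates: pd.DataFrame,
    degs: pd.DataFrame,
    methylation: pd.DataFrame,
    expression: pd.DataFrame,
    samples: list[str] | None = None,
    max_r: float = 0.0,
) -> pd.DataFrame:
    """Correlate candidate DMR methylation with expression across samples.

    ``candidates`` needs ``gene_id, kind, direction`` (DMR polarity);
    ``methylation`` and ``expression`` are genes x samples matrices of the
    per-gene DMR mean methylation ratio and normalized expression.  Pearson
    r is computed over the samples shared by both matrices (or ``samples``
    when given); genes with < 3 paired samples or a constant vector are
    flagged ``evaluated=False``.  Concordance requires ``r < max_r``
    (default 0: any negative correlation; a negative ``max_r`` tightens the
    criterion).  Output sorted by r ascending.
    """
    common = [
        s
        for s in (samples if samples is not None else methylation.columns)
        if s in methylation.columns and s in expression.columns
    ]
    deg_by_gene = degs.set_index("gene_id")

    rows = []
    for cand in candidates.itertuples(index=False):
        gene = cand.gene_id
        r = np.nan
        evaluated = False
        if gene in methylation.index and gene in expression.index and len(common) >= 3:
            m = methylation.loc[gene, common].to_numpy(dtype=float)
            e = expression.loc[gene, common].to_numpy(dtype=float)
            ok = ~(np.isnan(m) | np.isnan(e))
            m, e = m[ok], e[ok]
            if len(m) >= 3 and np.ptp(m) > 0 and np.ptp(e) > 0:
                r = float(np.corrcoef(m, e)[0, 1])
                evaluated = True
        deg_dir = ""
        if gene in deg_by_gene.index:
            rec = deg_by_gene.loc[gene]
            if bool(rec["is_deg"]):
                deg_dir = "up" if rec["log2_fold_change"] > 0 else "down"
        concordant = (
            evaluated
            and r < max_r
            and (
                (cand.direction == "Hyper" and deg_dir == "down")
                or (cand.direction == "Hypo" and deg_dir == "up")
            )
        )
        rows.append(
            {
                "gene_id": gene,
                "kind": cand.kind,
                "dmr_direction": cand.direction,
                "deg_direction": deg_dir,
                "pearson_r": r,
                "concordant": concordant,
                "evaluated": evaluated,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "kind",
            "dmr_direction",
            "deg_direction",
            "pearson_r",
            "concordant",
            "evaluated",
        ],
    )
    return out.sort_values("pearson_r", na_position="last", kind="stable").reset_index(drop=True)
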