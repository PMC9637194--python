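"""End-to-end orchestration: files in, call tables + summary JSON out.

``run_all`` wires the stages in dependency order (DMC calling ->
trajectories -> shared sets -> DMRs -> driver/booster/predictor discovery
-> PDOX filtering -> expression integration -> cohort metrics), writing
every intermediate as a TSV so each CLI subcommand can be re-run standalone
on the emitted files.  The summary JSON is versioned and fully determined
by the inputs and thresholds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_sets, discovery, dmc, expression, metrics, regions, trajectory
from . import io as eio
from .errors import ConfigurationError, EmptySelectionError

log = logging.getLogger("epirelapse")

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Paths and thresholds of a full pipeline run.

    Threshold defaults are the analysis constants used throughout:
    coverage >= 5 reads; DMC at |delta| >= 0.2 and q <= 0.05; the stricter
    driver consistency filter at mean |delta| > 0.3; predictor top flag at
    |delta| >= 0.8; TSS window +-5 kb; DMR merge gap 300 bp with >= 3 DMCs;
    DEG at q <= 0.05 and |log2FC| >= 1.
    """

    meth_dir: str = ""
    sample_sheet: str = ""
    annotation: str = ""
    counts: str = ""
    out_dir: str = "results"

    min_reads: int = 5
    dmc_delta: float = 0.2
    dmc_q: float = 0.05
    driver_delta: float = 0.3
    predictor_delta: float = 0.8
    tss_window: int = 5000
    dmr_max_gap: int = 300
    dmr_min_dmcs: int = 3
    deg_q: float = 0.05
    deg_log2fc: float = 1.0
    top_k: int = 20_000
    seed: int = 0

    def validate(self) -> None:
        if self.min_reads < 1:
            raise ConfigurationError("min_reads: must be >= 1")
        for name in ("dmc_delta", "driver_delta"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name}: must be in [0, 1]")
        for name in ("dmc_q", "deg_q"):
            if not 0 < getattr(self, name) <= 1:
                raise ConfigurationError(f"{name}: must be in (0, 1]")
        if not 0 <= self.predictor_delta <= 1:
            raise ConfigurationError("predictor_delta: must be in [0, 1]")
        for name in ("tss_window", "dmr_max_gap"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be >= 0")
        if self.dmr_min_dmcs < 1:
            raise ConfigurationError("dmr_min_dmcs: must be >= 1")
        if self.deg_log2fc < 0:
            raise ConfigurationError("deg_log2fc: must be >= 0")
        if self.top_k < 1:
            raise ConfigurationError("top_k: must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{sorted(unknown)[0]}: unknown configuration field")
        return cls(**raw)


def _states_str(states: tuple) -> str:
    return ";".join(states)


def _candidate_gene_table(
    cand: pd.DataFrame,
    deltas: pd.DataFrame,
    genes: pd.DataFrame,
    kind: str,
    max_gap: int,
    min_dmcs: int,
    window: int,
    delta_samples: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """DMCs -> DMRs -> TSS-window genes for one candidate kind.

    Returns (dmrs, associations, gene-level candidate frame).  The per-site
    delta used for DMR means is the mean over ``delta_samples`` (all tumor
    samples when None).
    """
    if cand.empty:
        empty = pd.DataFrame(columns=["gene_id", "kind", "direction", "sites"])
        return pd.DataFrame(columns=regions.DMR_COLUMNS), pd.DataFrame(), empty
    use = deltas[delta_samples] if delta_samples else deltas
    site_delta = use.mean(axis=1)
    df = cand[["chrom", "start", "direction"]].copy()
    df["delta"] = [
        float(site_delta.get((c, s), np.nan)) for c, s in zip(df["chrom"], df["start"])
    ]
    df = eio.sort_sites(df)
    dmrs = regions.merge_dmrs(df, max_gap=max_gap, min_dmcs=min_dmcs)
    assoc = regions.assign_genes(dmrs, genes, window=window)
    if assoc.empty:
        empty = pd.DataFrame(columns=["gene_id", "kind", "direction", "sites"])
        return dmrs, assoc, empty

    site_lists = {
        (r.chrom, r.start, r.end): r.sites for r in dmrs.itertuples(index=False)
    }
    rows = []
    for (gene, direction), grp in assoc.groupby(["gene_id", "direction"], sort=True):
        sites: list = []
        for r in grp.itertuples(index=False):
            sites.extend(site_lists[(r.chrom, r.dmr_start, r.dmr_end)])
        rows.append(dict(gene_id=gene, kind=kind, direction=direction, sites=sites))
    return dmrs, assoc, pd.DataFrame(rows)


def analyze_cohort(cohort, config: PipelineConfig | None = None) -> dict:
    """In-memory discovery pass over a :class:`~epirelapse.SimulatedCohort`.

    Runs coverage filtering, DMC calling, trajectory classification and the
    three discovery procedures directly on the cohort's frames (no file
    round-trip).  Returns ``{"calls", "trajectories", "subtypes"}`` where
    each subtype entry carries ``drivers``, ``boosters``, ``predictors``
    and the per-site ``deltas`` matrix.
    """
    config = config or PipelineConfig()
    sheet = cohort.samples
    by_id = sheet.set_index("sample_id")

    calls: dict[str, pd.DataFrame] = {}
    for row in sheet.itertuples(index=False):
        if row.role in ("primary", "relapse", "pdox"):
            calls[row.sample_id] = dmc.call_dmcs(
                dmc.filter_coverage(cohort.methylation[row.sample_id], config.min_reads),
                dmc.filter_coverage(cohort.methylation[row.matched_normal_id], config.min_reads),
                delta_min=config.dmc_delta,
                q_max=config.dmc_q,
            )

    patient_samples: dict[str, list[str]] = {}
    for row in sheet.itertuples(index=False):
        if row.role in ("primary", "relapse"):
            patient_samples.setdefault(row.patient_id, []).append(row.sample_id)
    traj: dict[str, pd.DataFrame] = {}
    for pid, sids in sorted(patient_samples.items()):
        sids.sort(key=lambda s: int(by_id.loc[s, "timepoint"]))
        if len(sids) >= 2:
            traj[pid] = trajectory.build_state_sequences([calls[s] for s in sids])

    result = {"calls": calls, "trajectories": traj, "subtypes": {}}
    for subtype in ("RELA", "PFA"):
        tumors = sheet[(sheet["subtype"] == subtype) & sheet["role"].isin(["primary", "relapse"])]
        if tumors.empty:
            continue
        recurring = [
            p
            for p in sorted(tumors.loc[tumors["recurred"], "patient_id"].unique())
            if p in traj
        ]
        deltas = pd.DataFrame(
            {
                sid: calls[sid].set_index(["chrom", "start"])["delta"]
                for sid in tumors["sample_id"]
            }
        )
        drivers = discovery.find_drivers(
            {p: traj[p] for p in recurring}, deltas, delta_min=config.driver_delta
        )
        boosters = discovery.find_boosters({p: traj[p] for p in recurring})
        nonrec = tumors[(~tumors["recurred"]) & (tumors["role"] == "primary")]
        predictors = pd.DataFrame(columns=discovery.CANDIDATE_COLUMNS)
        if len(nonrec) and recurring:
            rec_primaries = {
                p: calls[
                    tumors.loc[
                        (tumors["patient_id"] == p) & (tumors["role"] == "primary"),
                        "sample_id",
                    ].iloc[0]
                ]
                for p in recurring
            }
            predictors = discovery.find_predictors(
                rec_primaries,
                [calls[s] for s in nonrec["sample_id"]],
                {s: calls[s] for s in tumors.loc[tumors["role"] == "relapse", "sample_id"]},
                delta_top=config.predictor_delta,
            )
        result["subtypes"][subtype] = {
            "drivers": drivers,
            "boosters": boosters,
            "predictors": predictors,
            "deltas": deltas,
        }
    return result


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the summary dictionary."""
    config.validate()
    out = Path(config.out_dir)
    for sub in ("dmc", "trajectory", "discovery", "expression", "metrics"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "thresholds": {
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(config)
            if f.name not in ("meth_dir", "sample_sheet", "annotation", "counts", "out_dir")
        },
    }

    stage = "inputs"
    try:
        sheet = eio.read_sample_sheet(config.sample_sheet)
        meth: dict[str, pd.DataFrame] = {}
        cpa: dict[str, pd.DataFrame] = {}
        meth_dir = Path(config.meth_dir)
        for sid in sheet["sample_id"]:
            meth[sid] = dmc.filter_coverage(
                eio.read_methylation_table(meth_dir / f"{sid}.cpg.bedgraph"), config.min_reads
            )
            cpa_path = meth_dir / f"{sid}.cpa.bedgraph"
            if cpa_path.exists():
                cpa[sid] = dmc.filter_coverage(
                    eio.read_methylation_table(cpa_path, context="CpA"), config.min_reads
                )
        genes = eio.read_gene_annotation(config.annotation) if config.annotation else None
        counts = eio.read_expression_counts(config.counts) if config.counts else None
        by_id = sheet.set_index("sample_id")
        summary["samples"] = {
            "n_samples": int(len(sheet)),
            "n_tumor": int(sheet["role"].isin(["primary", "relapse"]).sum()),
            "n_pdox": int((sheet["role"] == "pdox").sum()),
        }

        stage = "dmc"
        calls: dict[str, pd.DataFrame] = {}
        dmc_counts = {}
        for row in sheet.itertuples(index=False):
            if row.role not in ("primary", "relapse", "pdox"):
                continue
            table = dmc.call_dmcs(
                meth[row.sample_id],
                meth[row.matched_normal_id],
                delta_min=config.dmc_delta,
                q_max=config.dmc_q,
            )
            calls[row.sample_id] = table
            eio.write_table(table, out / "dmc" / f"{row.sample_id}.dmc.tsv")
            dmc_counts[row.sample_id] = {
                "n_hyper": int((table["direction"] == "Hyper").sum()),
                "n_hypo": int((table["direction"] == "Hypo").sum()),
            }
        summary["dmc"] = dmc_counts

        stage = "trajectory"
        patient_samples: dict[str, list[str]] = {}
        for row in sheet.itertuples(index=False):
            if row.role in ("primary", "relapse"):
                patient_samples.setdefault(row.patient_id, []).append(row.sample_id)
        for pid in patient_samples:
            patient_samples[pid].sort(key=lambda s: int(by_id.loc[s, "timepoint"]))

        traj: dict[str, pd.DataFrame] = {}
        summary["trajectory"] = {}
        for pid, sids in sorted(patient_samples.items()):
            if len(sids) < 2:
                continue
            t = trajectory.build_state_sequences([calls[s] for s in sids])
            traj[pid] = t
            flat = t[["chrom", "start", "category"]].copy()
            flat["states"] = t["states"].map(_states_str)
            eio.write_table(flat, out / "trajectory" / f"{pid}.trajectory.tsv")
            fr = trajectory.category_fractions(t)
            eio.write_table(
                fr.rename_axis("category").rename("fraction").reset_index(),
                out / "trajectory" / f"{pid}.fractions.tsv",
            )
            eio.write_table(
                trajectory.state_flow_counts(t), out / "trajectory" / f"{pid}.flows.tsv"
            )
            summary["trajectory"][pid] = {k: float(v) for k, v in fr.items()}

        stage = "discovery"
        summary["subtypes"] = {}
        integration_jobs = []
        for subtype in sorted(sheet.loc[sheet["role"].isin(["primary", "relapse"]), "subtype"].unique()):
            sub_sheet = sheet[(sheet["subtype"] == subtype)]
            tumors = sub_sheet[sub_sheet["role"].isin(["primary", "relapse"])]
            recurring = sorted(
                tumors.loc[tumors["recurred"], "patient_id"].unique()
            )
            recurring = [p for p in recurring if p in traj]
            sub_summary: dict = {}

            # shared consistent sets (UpSet semantics)
            if len(recurring) >= 2:
                for direction in ("Hyper", "Hypo"):
                    sets = {
                        p: trajectory.consistent_site_sets(traj[p])[direction]
                        for p in recurring
                    }
                    shared, tally = cohort_sets.intersect_patients(
                        sets, subtype=subtype, direction=direction
                    )
                    eio.write_table(
                        tally, out / "discovery" / f"{subtype}.upset_{direction.lower()}.tsv"
                    )
                    sub_summary[f"shared_consistent_{direction.lower()}"] = len(shared.sites)

            # per-site delta matrix over the subtype's tumor samples
            tumor_ids = list(tumors["sample_id"])
            delta_cols = {
                sid: calls[sid].set_index(["chrom", "start"])["delta"] for sid in tumor_ids
            }
            deltas = pd.DataFrame(delta_cols)

            drivers = (
                discovery.find_drivers(
                    {p: traj[p] for p in recurring}, deltas, delta_min=config.driver_delta
                )
                if recurring
                else pd.DataFrame(columns=discovery.CANDIDATE_COLUMNS)
            )
            boosters = (
                discovery.find_boosters({p: traj[p] for p in recurring})
                if recurring
                else pd.DataFrame(columns=discovery.CANDIDATE_COLUMNS)
            )
            relapse_ids = list(tumors.loc[tumors["role"] == "relapse", "sample_id"])
            if len(boosters):
                rel_mean = deltas[relapse_ids].mean(axis=1)
                boosters["mean_delta"] = [
                    float(rel_mean.get((c, s), np.nan))
                    for c, s in zip(boosters["chrom"], boosters["start"])
                ]

            nonrec = tumors[(~tumors["recurred"]) & (tumors["role"] == "primary")]
            predictors = pd.DataFrame(columns=discovery.CANDIDATE_COLUMNS)
            if len(nonrec) and recurring:
                rec_primaries = {
                    p: calls[f]
                    for p in recurring
                    for f in tumors.loc[
                        (tumors["patient_id"] == p) & (tumors["role"] == "primary"),
                        "sample_id",
                    ]
                }
                predictors = discovery.find_predictors(
                    rec_primaries,
                    [calls[s] for s in nonrec["sample_id"]],
                    {s: calls[s] for s in relapse_ids},
                    delta_top=config.predictor_delta,
                )
            else:
                log.warning("%s: no non-recurrent reference primary; predictors skipped", subtype)

            # PDOX evidence (site- and gene-level)
            pdox_ids = list(sub_sheet.loc[sub_sheet["role"] == "pdox", "sample_id"])
            site_ev = {
                sid: {
                    ((r.chrom, r.start), r.direction)
                    for r in calls[sid].itertuples(index=False)
                    if r.direction != "NoChange"
                }
                for sid in pdox_ids
            }
            drivers = discovery.pdox_filter(drivers, site_ev)
            boosters = discovery.pdox_filter(boosters, site_ev)
            eio.write_table(drivers, out / "discovery" / f"{subtype}.drivers.tsv")
            eio.write_table(boosters, out / "discovery" / f"{subtype}.boosters.tsv")
            eio.write_table(predictors, out / "discovery" / f"{subtype}.predictors.tsv")
            sub_summary["n_drivers"] = int(len(drivers))
            sub_summary["n_boosters"] = int(len(boosters))
            sub_summary["n_predictors"] = int(len(predictors))
            sub_summary["n_predictors_top"] = (
                int(predictors["top"].sum()) if "top" in predictors else 0
            )

            if genes is not None:
                _, _, driver_genes = _candidate_gene_table(
                    drivers, deltas, genes, "driver",
                    config.dmr_max_gap, config.dmr_min_dmcs, config.tss_window,
                )
                _, _, booster_genes = _candidate_gene_table(
                    boosters, deltas, genes, "booster",
                    config.dmr_max_gap, config.dmr_min_dmcs, config.tss_window,
                    delta_samples=relapse_ids,
                )
                gene_ev = {}
                for sid in pdox_ids:
                    t = calls[sid]
                    sites = t[t["direction"] != "NoChange"][["chrom", "start", "direction", "delta"]]
                    sites = eio.sort_sites(sites)
                    pdox_dmrs = regions.merge_dmrs(
                        sites, max_gap=config.dmr_max_gap, min_dmcs=config.dmr_min_dmcs
                    )
                    assoc = regions.assign_genes(pdox_dmrs, genes, window=config.tss_window)
                    gene_ev[sid] = (
                        set(zip(assoc["gene_id"], assoc["direction"])) if len(assoc) else set()
                    )
                gene_cands = pd.concat([driver_genes, booster_genes], ignore_index=True)
                gene_cands = discovery.pdox_filter(
                    gene_cands, gene_ev, key_columns=("gene_id",)
                )
                eio.write_table(
                    gene_cands.drop(columns=["sites"]),
                    out / "discovery" / f"{subtype}.candidate_genes.tsv",
                )
                pres = discovery.preservation_summary(gene_cands)
                eio.write_table(pres, out / "discovery" / f"{subtype}.preservation.tsv")
                sub_summary["n_driver_genes"] = int((gene_cands["kind"] == "driver").sum())
                sub_summary["n_booster_genes"] = int((gene_cands["kind"] == "booster").sum())
                sub_summary["preservation"] = pres.to_dict(orient="records")
                integration_jobs.append((subtype, tumors, gene_cands))
            summary["subtypes"][subtype] = sub_summary

        stage = "expression"
        if counts is not None:
            for subtype, tumors, gene_cands in integration_jobs:
                tumor_cols = [s for s in tumors["sample_id"] if s in counts.columns]
                normal_cols = [
                    s
                    for s in sheet.loc[
                        (sheet["subtype"] == subtype)
                        & sheet["role"].str.startswith("normal"),
                        "sample_id",
                    ]
                    if s in counts.columns
                ]
                if len(tumor_cols) < 2 or len(normal_cols) < 2:
                    log.warning("%s: not enough expression samples; DEGs skipped", subtype)
                    continue
                degs = expression.call_degs(
                    counts, tumor_cols, normal_cols,
                    q_max=config.deg_q, min_abs_log2fc=config.deg_log2fc,
                )
                eio.write_table(degs, out / "expression" / f"{subtype}.degs.tsv")
                summary["subtypes"][subtype]["n_degs"] = int(degs["is_deg"].sum())
                if len(gene_cands):
                    ratio_cols = tumor_cols + normal_cols
                    ratio_idx = {
                        sid: meth[sid].set_index(["chrom", "start"])["ratio"]
                        for sid in ratio_cols
                    }
                    gene_meth = pd.DataFrame(
                        {
                            sid: {
                                r.gene_id: float(
                                    np.nanmean(
                                        [
                                            float(ratio_idx[sid].get(site, np.nan))
                                            for site in r.sites
                                        ]
                                    )
                                )
                                for r in gene_cands.itertuples(index=False)
                            }
                            for sid in ratio_cols
                        }
                    )
                    expr = np.log2(expression.cpm(counts[ratio_cols]) + 1.0)
                    integrated = expression.integrate(gene_cands, degs, gene_meth, expr)
                    eio.write_table(
                        integrated, out / "expression" / f"{subtype}.integrated.tsv"
                    )
                    summary["subtypes"][subtype]["n_concordant_genes"] = int(
                        integrated["concordant"].sum()
                    )

        stage = "metrics"
        conv_rows = []
        summary["convergence"] = {}
        for pid, sids in sorted(patient_samples.items()):
            if len(sids) < 2:
                continue
            series = metrics.convergence_series(
                [(s, int(by_id.loc[s, "timepoint"]), meth[s]) for s in sids],
                min_reads=config.min_reads,
            )
            conv_rows.append(series.assign(patient_id=pid))
            summary["convergence"][pid] = [round(float(r), 6) for r in series["pearson_r"]]
        if conv_rows:
            eio.write_table(pd.concat(conv_rows, ignore_index=True), out / "metrics" / "convergence.tsv")

        summary["pdox_fidelity"] = {}
        for row in sheet.itertuples(index=False):
            if row.role == "pdox":
                r, n_shared = metrics.global_fidelity(
                    meth[row.pdox_of], meth[row.sample_id], min_reads=config.min_reads
                )
                summary["pdox_fidelity"][row.sample_id] = round(float(r), 6)

        ratio_matrix = pd.DataFrame(
            {
                sid: meth[sid].set_index(["chrom", "start"])["ratio"]
                for sid in sheet["sample_id"]
            }
        )
        try:
            k = min(config.top_k, int(ratio_matrix.dropna(how="any").shape[0]))
            top = metrics.top_variable_cpgs(ratio_matrix, k)
            eio.write_table(
                top.index.to_frame(index=False), out / "metrics" / "top_variable_sites.tsv"
            )
            summary["top_variable"] = {"k": k, "n_eligible": int(ratio_matrix.dropna(how="any").shape[0])}
        except EmptySelectionError as exc:
            log.warning("top-variable selection skipped: %s", exc)

        if cpa:
            summary["cpa_mean"] = {
                sid: round(dmc.summarize_context(df, "CpA"), 6) for sid, df in sorted(cpa.items())
            }

    except Exception:
        log.exception("pipeline failed at stage %r", stage)
        raise

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
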