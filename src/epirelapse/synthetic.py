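"""Synthetic serial-relapse RRBS cohort with planted ground truth.

The generator emulates the statistical structure a longitudinal methylation
analysis of serially relapsing tumors assumes, so every downstream stage is
testable without external data:

* a bimodal CpG baseline per normal tissue (Beta(1,10)/Beta(10,1) mixture,
  weights 0.55/0.45);
* per-patient tumor methylomes that drift toward a patient-specific
  "attractor" profile at each relapse (mixing weight ``convergence_rate``),
  reproducing the rising consecutive-relapse correlation of convergent
  epigenetic reprogramming, with a decaying load of transient "in-transit"
  changes;
* planted signal clusters: **driver** sites shifted in the primary and every
  relapse of every patient, **booster** sites shifted in relapses only,
  **predictor** sites shifted (|delta| >= 0.8) in recurring patients'
  primaries and relapses but not in the non-recurrent reference primary,
  and **switch** sites shifted at a random proper subset of timepoints;
* read counts: total ~ Poisson(mean_coverage) per site and sample,
  methylated ~ Binomial(total, ratio); sites drawn with zero coverage are
  absent from the sample's table;
* PDOX models copying their source sample's ratios plus truncated Gaussian
  noise;
* gene TSSs placed next to planted clusters for a subset of
  methylation-coupled genes whose negative-binomial expression decreases
  log-linearly with promoter methylation;
* a low-methylation CpA compartment globally reduced in tumors.

Everything is a deterministic function of the config and its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .errors import ConfigurationError

SITE_LABELS = (
    "baseline",
    "driver_hyper",
    "driver_hypo",
    "booster_hyper",
    "booster_hypo",
    "predictor_hyper",
    "predictor_hypo",
    "switch",
)


@dataclass
class CohortConfig:
    """Study conditions of the simulated cohort.

    Defaults mirror a two-subtype serial-relapse cohort: five recurring
    patients per subtype with relapse counts {7,2,1,4,1} (RELA, referenced
    to normal cerebrum) and {3,2,1,2,3} (PFA, referenced to normal
    cerebellum), plus one non-recurrent primary per subtype and one PDOX
    model per recurring patient (taken from the last relapse).
    """

    n_patients_per_subtype: int = 5
    n_relapses_per_patient: Mapping[str, Sequence[int]] = field(
        default_factory=lambda: {"RELA": (7, 2, 1, 4, 1), "PFA": (3, 2, 1, 2, 3)}
    )
    n_sites: int = 50_000
    n_chroms: int = 5
    mean_coverage: float = 50.0
    n_driver_sites: int = 150
    n_booster_sites: int = 150
    n_predictor_sites: int = 150
    n_switch_sites: int = 200
    delta_driver: float = 0.5
    delta_booster: float = 0.5
    delta_predictor: float = 0.8
    convergence_rate: float = 0.6
    pdox_noise_sd: float = 0.05
    n_genes: int = 2000
    frac_genes_methylation_coupled: float = 0.03
    include_nonrecurrent_primary: bool = True
    seed: int = 0

    # secondary shape parameters (see docs for rationale)
    n_normals_per_tissue: int = 5
    n_cpa_sites: int = 2000
    cpa_tumor_scale: float = 0.3
    cluster_size: int = 5
    attractor_flip_fraction: float = 0.10
    transient_flip_fraction: float = 0.05
    primary_attractor_mix: float = 0.3
    ratio_jitter_sd: float = 0.02
    expression_slope: float = -3.0
    expression_dispersion: float = 20.0
    expression_base_mean: float = 300.0
    expression_base_sigma: float = 0.75

    def validate(self) -> None:
        def bad(name: str, why: str):
            raise ConfigurationError(f"{name}: {why}")

        if self.n_patients_per_subtype < 1:
            bad("n_patients_per_subtype", "must be >= 1")
        for subtype in ("RELA", "PFA"):
            counts = self.n_relapses_per_patient.get(subtype)
            if counts is None or len(counts) != self.n_patients_per_subtype:
                bad(
                    "n_relapses_per_patient",
                    f"needs {self.n_patients_per_subtype} entries for {subtype}",
                )
            if any(k < 1 for k in counts):
                bad("n_relapses_per_patient", "every recurring patient needs >= 1 relapse")
        if self.n_sites < 1:
            bad("n_sites", "must be positive")
        if self.n_chroms < 1:
            bad("n_chroms", "must be >= 1")
        if self.mean_coverage <= 0:
            bad("mean_coverage", "must be positive")
        planted = (
            self.n_driver_sites
            + self.n_booster_sites
            + self.n_predictor_sites
            + self.n_switch_sites
        )
        if planted > self.n_sites:
            bad("n_sites", "planted sites exceed n_sites")
        if self.cluster_size < 3:
            bad("cluster_size", "must be >= 3")
        for name in ("n_driver_sites", "n_booster_sites", "n_predictor_sites"):
            if getattr(self, name) % self.cluster_size != 0:
                bad(name, f"must be a multiple of cluster_size={self.cluster_size}")
        if planted * 4 > self.n_sites:
            bad("n_sites", "too small to separate the planted clusters")
        for name in ("delta_driver", "delta_booster"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                bad(name, "must be in (0, 1]")
        if not 0.8 <= self.delta_predictor <= 1:
            bad("delta_predictor", "must be in [0.8, 1]")
        for name in (
            "convergence_rate",
            "frac_genes_methylation_coupled",
            "attractor_flip_fraction",
            "transient_flip_fraction",
            "primary_attractor_mix",
            "cpa_tumor_scale",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                bad(name, "must be in [0, 1]")
        for name in ("pdox_noise_sd", "ratio_jitter_sd"):
            if getattr(self, name) < 0:
                bad(name, "must be >= 0")
        if self.n_genes < 1:
            bad("n_genes", "must be >= 1")
        if self.n_normals_per_tissue < 1:
            bad("n_normals_per_tissue", "must be >= 1")
        if self.expression_dispersion <= 0:
            bad("expression_dispersion", "must be positive")


@dataclass
class TruthTable:
    """Planted ground truth: per-site labels, per-gene labels, attractors."""

    sites: pd.DataFrame  # chrom, start, label, direction, cluster_id
    genes: pd.DataFrame  # gene_id, label, cluster_id
    attractors: pd.DataFrame  # sample_id, attractor (patient id or '')

    def planted_sites(self, kind: str) -> set:
        mask = self.sites["label"].str.startswith(kind)
        return set(zip(self.sites.loc[mask, "chrom"], self.sites.loc[mask, "start"]))


@dataclass
class SimulatedCohort:
    config: CohortConfig
    samples: pd.DataFrame
    methylation: dict  # sample_id -> CpG table
    methylation_cpa: dict  # sample_id -> CpA table
    genes: pd.DataFrame
    expression: pd.DataFrame
    truth: TruthTable
    true_ratios: pd.DataFrame  # CpG design ratios, sites x samples


def _flip(rng: np.random.Generator, values: np.ndarray) -> np.ndarray:
    """Replace each ratio by a draw from the opposite methylation mode."""
    low = rng.uniform(0.05, 0.25, len(values))
    high = rng.uniform(0.75, 0.95, len(values))
    return np.where(values < 0.5, high, low)


def _planted_baseline(rng: np.random.Generator, n: int, delta: float, hyper: bool) -> np.ndarray:
    hi = min(0.08, 1.0 - delta)
    lo = min(0.02, hi / 2.0)
    b = rng.uniform(lo, hi, n)
    return b if hyper else 1.0 - b


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    csize = config.cluster_size

    # --- site scaffold -----------------------------------------------------
    per_chrom = np.full(config.n_chroms, n // config.n_chroms)
    per_chrom[: n % config.n_chroms] += 1
    chrom_of = np.repeat(np.arange(config.n_chroms), per_chrom)
    chrom_names = np.array([f"chr{i + 1}" for i in range(config.n_chroms)])

    n_clusters = (
        config.n_driver_sites + config.n_booster_sites + config.n_predictor_sites
    ) // csize
    step = max(csize * 4, 1)
    candidates = np.array(
        [
            i
            for i in range(0, n - csize, step)
            if chrom_of[i] == chrom_of[i + csize - 1]
        ]
    )
    if len(candidates) < n_clusters:
        raise ConfigurationError("n_sites: too small to place the planted clusters")
    starts = rng.permutation(candidates)[:n_clusters]
    cluster_sites = [np.arange(s, s + csize) for s in starts]
    n_dc = config.n_driver_sites // csize
    n_bc = config.n_booster_sites // csize
    cluster_kind = (
        ["driver"] * n_dc + ["booster"] * n_bc + ["predictor"] * (n_clusters - n_dc - n_bc)
    )
    cluster_delta = {
        "driver": config.delta_driver,
        "booster": config.delta_booster,
        "predictor": config.delta_predictor,
    }
    cluster_hyper = rng.random(n_clusters) < 0.5

    planted_idx = np.concatenate(cluster_sites) if n_clusters else np.array([], dtype=int)
    background = np.setdiff1d(np.arange(n), planted_idx)
    switch_idx = rng.choice(background, size=config.n_switch_sites, replace=False)
    switch_hyper = rng.random(config.n_switch_sites) < 0.5
    background = np.setdiff1d(background, switch_idx)

    gaps = rng.integers(500, 2001, n)
    for sites in cluster_sites:
        gaps[sites[1:]] = rng.integers(30, 120, csize - 1)
    positions = np.empty(n, dtype=np.int64)
    for c in range(config.n_chroms):
        mask = chrom_of == c
        positions[mask] = 1000 + np.cumsum(gaps[mask])
    chroms = chrom_names[chrom_of]

    # --- baselines ---------------------------------------------------------
    mode = rng.random(n) < 0.55
    base = np.where(mode, rng.beta(1, 10, n), rng.beta(10, 1, n))
    planted_design = np.zeros(n)  # design tumor value at planted sites
    for sites, kind, hyper in zip(cluster_sites, cluster_kind, cluster_hyper):
        delta = cluster_delta[kind]
        b = _planted_baseline(rng, csize, delta, hyper)
        base[sites] = b
        planted_design[sites] = b + delta if hyper else b - delta
    b = _planted_baseline(rng, config.n_switch_sites, config.delta_driver, True)
    base[switch_idx] = np.where(switch_hyper, b, 1.0 - b)
    planted_design[switch_idx] = np.where(
        switch_hyper, base[switch_idx] + config.delta_driver, base[switch_idx] - config.delta_driver
    )

    tissue_base = {}
    for tissue in ("cerebrum", "cerebellum"):
        t = base.copy()
        flips = rng.choice(background, size=int(round(0.02 * len(background))), replace=False)
        t[flips] = _flip(rng, t[flips])
        tissue_base[tissue] = t

    # --- sample bookkeeping ------------------------------------------------
    tissue_for = {"RELA": "cerebrum", "PFA": "cerebellum"}
    sheet_rows: list[dict] = []
    true_cols: dict[str, np.ndarray] = {}
    attractor_of: dict[str, str] = {}

    normal_ids = {}
    for subtype in ("RELA", "PFA"):
        tissue = tissue_for[subtype]
        role = eio.NORMAL_TISSUE_FOR_SUBTYPE[subtype]
        ids = []
        for i in range(config.n_normals_per_tissue):
            sid = f"N-{tissue}-{i + 1}"
            prof = tissue_base[tissue].copy()
            prof[background] = np.clip(
                prof[background] + rng.normal(0, config.ratio_jitter_sd, len(background)),
                0,
                1,
            )
            true_cols[sid] = prof
            attractor_of[sid] = ""
            sheet_rows.append(
                dict(
                    sample_id=sid,
                    patient_id=f"{tissue}-donor-{i + 1}",
                    subtype=subtype,
                    role=role,
                    timepoint=-1,
                    matched_normal_id="",
                    pdox_of="",
                    recurred=False,
                )
            )
            ids.append(sid)
        normal_ids[subtype] = ids

    def overlay_planted(profile: np.ndarray, timepoint: int, recurred: bool, shifted_switch) -> None:
        for sites, kind, hyper in zip(cluster_sites, cluster_kind, cluster_hyper):
            if kind == "driver":
                profile[sites] = planted_design[sites]
            elif kind == "booster":
                profile[sites] = planted_design[sites] if timepoint >= 1 else base[sites]
            elif kind == "predictor":
                profile[sites] = planted_design[sites] if recurred else base[sites]
        for j, site in enumerate(switch_idx):
            profile[site] = (
                planted_design[site] if timepoint in shifted_switch[j] else base[site]
            )

    pdox_sources: list[tuple[str, str, str]] = []  # (pdox_id, source_id, subtype)

    for subtype in ("RELA", "PFA"):
        tissue = tissue_for[subtype]
        tbase = tissue_base[tissue]
        matched = normal_ids[subtype][0]
        relapse_counts = list(config.n_relapses_per_patient[subtype])
        patient_specs = [(f"{subtype}{i + 1}", k, True) for i, k in enumerate(relapse_counts)]
        if config.include_nonrecurrent_primary:
            patient_specs.append((f"{subtype}{len(relapse_counts) + 1}", 0, False))

        for patient, n_rel, recurred in patient_specs:
            attractor = tbase.copy()
            flips = rng.choice(
                background,
                size=int(round(config.attractor_flip_fraction * len(background))),
                replace=False,
            )
            attractor[flips] = _flip(rng, attractor[flips])

            timepoints = list(range(n_rel + 1))
            shifted_switch = []
            for _ in range(config.n_switch_sites):
                if len(timepoints) < 2:
                    shifted_switch.append(frozenset())
                else:
                    size = int(rng.integers(1, len(timepoints)))
                    shifted_switch.append(
                        frozenset(rng.choice(timepoints, size=size, replace=False).tolist())
                    )

            heritable = tbase.copy()
            m0 = config.primary_attractor_mix
            heritable[background] = (
                (1 - m0) * tbase[background] + m0 * attractor[background]
            )
            c = config.convergence_rate
            for t in timepoints:
                if t >= 1:
                    nxt = heritable.copy()
                    nxt[background] = (
                        (1 - c) * heritable[background] + c * attractor[background]
                    )
                    heritable = nxt
                f_trans = config.transient_flip_fraction * (1 - c) ** t
                n_trans = int(round(f_trans * len(background)))
                if n_trans:
                    hit = rng.choice(background, size=n_trans, replace=False)
                    heritable[hit] = _flip(rng, heritable[hit])

                measured = heritable.copy()
                measured[background] = np.clip(
                    measured[background]
                    + rng.normal(0, config.ratio_jitter_sd, len(background)),
                    0,
                    1,
                )
                overlay_planted(measured, t, recurred, shifted_switch)
                overlay_planted(heritable, t, recurred, shifted_switch)

                sid = f"{patient}-P" if t == 0 else f"{patient}-R{t}"
                true_cols[sid] = measured
                attractor_of[sid] = patient
                sheet_rows.append(
                    dict(
                        sample_id=sid,
                        patient_id=patient,
                        subtype=subtype,
                        role="primary" if t == 0 else "relapse",
                        timepoint=t,
                        matched_normal_id=matched,
                        pdox_of="",
                        recurred=recurred,
                    )
                )
            if recurred:
                source = f"{patient}-R{n_rel}"
                pdox_sources.append((f"PDOX-{source}", source, subtype))

    for pdox_id, source, subtype in pdox_sources:
        prof = true_cols[source].copy()
        if config.pdox_noise_sd > 0:
            prof = np.clip(prof + rng.normal(0, config.pdox_noise_sd, n), 0, 1)
        true_cols[pdox_id] = prof
        src_row = next(r for r in sheet_rows if r["sample_id"] == source)
        attractor_of[pdox_id] = src_row["patient_id"]
        sheet_rows.append(
            dict(
                sample_id=pdox_id,
                patient_id=src_row["patient_id"],
                subtype=subtype,
                role="pdox",
                timepoint=src_row["timepoint"],
                matched_normal_id=src_row["matched_normal_id"],
                pdox_of=source,
                recurred=src_row["recurred"],
            )
        )

    samples = pd.DataFrame(sheet_rows, columns=eio.SHEET_COLUMNS)

    # --- CpA compartment ---------------------------------------------------
    n_cpa = config.n_cpa_sites
    cpa_chrom_of = np.repeat(
        np.arange(config.n_chroms),
        np.diff(np.linspace(0, n_cpa, config.n_chroms + 1).astype(int)),
    )
    cpa_positions = np.empty(n_cpa, dtype=np.int64)
    cpa_gaps = rng.integers(801, 3001, n_cpa)
    for cidx in range(config.n_chroms):
        mask = cpa_chrom_of == cidx
        cpa_positions[mask] = 501 + np.cumsum(cpa_gaps[mask])
    cpa_chroms = chrom_names[cpa_chrom_of]
    cpa_base = rng.beta(2, 8, n_cpa)
    cpa_cols: dict[str, np.ndarray] = {}
    for row in sheet_rows:
        sid = row["sample_id"]
        if row["role"].startswith("normal"):
            prof = cpa_base
        elif row["role"] == "pdox":
            prof = cpa_cols[row["pdox_of"]]
            if config.pdox_noise_sd > 0:
                prof = prof + rng.normal(0, config.pdox_noise_sd, n_cpa)
        else:
            prof = cpa_base * config.cpa_tumor_scale + rng.normal(
                0, config.ratio_jitter_sd, n_cpa
            )
        cpa_cols[sid] = np.clip(prof, 0, 1)

    # --- sequencing counts -------------------------------------------------
    def draw_counts(chrom_arr, pos_arr, ratios, context) -> pd.DataFrame:
        total = rng.poisson(config.mean_coverage, len(ratios))
        meth = rng.binomial(total, np.clip(ratios, 0, 1))
        keep = total > 0
        tot = total[keep]
        return pd.DataFrame(
            {
                "chrom": chrom_arr[keep],
                "start": pos_arr[keep],
                "end": pos_arr[keep] + 2,
                "ratio": meth[keep] / tot,
                "meth_reads": meth[keep],
                "total_reads": tot,
                "context": context,
            }
        )

    methylation = {}
    methylation_cpa = {}
    for row in sheet_rows:
        sid = row["sample_id"]
        methylation[sid] = draw_counts(chroms, positions, true_cols[sid], "CpG")
        methylation_cpa[sid] = draw_counts(cpa_chroms, cpa_positions, cpa_cols[sid], "CpA")

    # --- genes and expression ---------------------------------------------
    # expression is coupled only to persistent marks (driver/predictor
    # clusters): booster marks arise mid-course, so a tumor-wide DEG truth
    # would be ill-defined for them
    persistent = np.array(
        [cl for cl, kind in enumerate(cluster_kind) if kind in ("driver", "predictor")],
        dtype=int,
    )
    n_coupled = min(
        int(round(config.frac_genes_methylation_coupled * config.n_genes)), len(persistent)
    )
    coupled_clusters = rng.permutation(persistent)[:n_coupled] if len(persistent) else []
    gene_rows = []
    gene_truth_rows = []
    chrom_span = {
        chrom_names[c]: int(positions[chrom_of == c].max()) if (chrom_of == c).any() else 10_000
        for c in range(config.n_chroms)
    }
    for g, cl in enumerate(coupled_clusters):
        first = cluster_sites[cl][0]
        tss = max(0, int(positions[first]) - int(rng.integers(200, 2001)))
        gid = f"G{g + 1:05d}"
        gene_rows.append(
            dict(gene_id=gid, chrom=chroms[first], tss=tss, strand="+" if rng.random() < 0.5 else "-")
        )
        label = "hyper_down" if cluster_hyper[cl] else "hypo_up"
        gene_truth_rows.append(dict(gene_id=gid, label=label, cluster_id=int(cl)))
    for g in range(n_coupled, config.n_genes):
        cname = chrom_names[int(rng.integers(0, config.n_chroms))]
        tss = int(rng.integers(0, chrom_span[cname]))
        gid = f"G{g + 1:05d}"
        gene_rows.append(
            dict(gene_id=gid, chrom=cname, tss=tss, strand="+" if rng.random() < 0.5 else "-")
        )
        gene_truth_rows.append(dict(gene_id=gid, label="unlinked", cluster_id=-1))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss", "strand"])

    expr_samples = [r["sample_id"] for r in sheet_rows if r["role"] != "pdox"]
    base_mean = rng.lognormal(
        np.log(config.expression_base_mean), config.expression_base_sigma, config.n_genes
    )
    mu = np.tile(base_mean[:, None], (1, len(expr_samples)))
    for g, cl in enumerate(coupled_clusters):
        sites = cluster_sites[cl]
        meth = np.array([true_cols[s][sites].mean() for s in expr_samples])
        mu[g] = base_mean[g] * np.power(2.0, config.expression_slope * meth)
    lib = rng.lognormal(0.0, 0.15, len(expr_samples))
    mu = np.maximum(mu * lib[None, :], 1e-8)
    disp = config.expression_dispersion
    counts = rng.negative_binomial(disp, disp / (disp + mu))
    expression = pd.DataFrame(
        counts, index=[r["gene_id"] for r in gene_rows], columns=expr_samples
    )
    expression.index.name = "gene_id"

    # --- truth tables ------------------------------------------------------
    label = np.array(["baseline"] * n, dtype=object)
    direction = np.array([""] * n, dtype=object)
    cluster_id = np.full(n, -1)
    for cl, (sites, kind, hyper) in enumerate(zip(cluster_sites, cluster_kind, cluster_hyper)):
        label[sites] = f"{kind}_{'hyper' if hyper else 'hypo'}"
        direction[sites] = "Hyper" if hyper else "Hypo"
        cluster_id[sites] = cl
    label[switch_idx] = "switch"
    direction[switch_idx] = np.where(switch_hyper, "Hyper", "Hypo")
    truth_sites = pd.DataFrame(
        {
            "chrom": chroms,
            "start": positions,
            "label": label,
            "direction": direction,
            "cluster_id": cluster_id,
        }
    )
    truth = TruthTable(
        sites=truth_sites,
        genes=pd.DataFrame(gene_truth_rows, columns=["gene_id", "label", "cluster_id"]),
        attractors=pd.DataFrame(
            {
                "sample_id": [r["sample_id"] for r in sheet_rows],
                "attractor": [attractor_of[r["sample_id"]] for r in sheet_rows],
            }
        ),
    )

    true_ratios = pd.DataFrame(
        {sid: true_cols[sid] for sid in (r["sample_id"] for r in sheet_rows)},
        index=pd.MultiIndex.from_arrays([chroms, positions], names=["chrom", "start"]),
    )

    return SimulatedCohort(
        config=config,
        samples=samples,
        methylation=methylation,
        methylation_cpa=methylation_cpa,
        genes=genes,
        expression=expression,
        truth=truth,
        true_ratios=true_ratios,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["n_relapses_per_patient"] = {k: list(v) for k, v in d["n_relapses_per_patient"].items()}
    return d


def config_from_dict(d: Mapping) -> CohortConfig:
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"{sorted(unknown)[0]}: unknown configuration field")
    kwargs = dict(d)
    if "n_relapses_per_patient" in kwargs:
        kwargs["n_relapses_per_patient"] = {
            k: tuple(v) for k, v in kwargs["n_relapses_per_patient"].items()
        }
    return CohortConfig(**kwargs)


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write the full cohort as plain-text tables under ``outdir``."""
    outdir = Path(outdir)
    meth_dir = outdir / "methylation"
    truth_dir = outdir / "truth"
    meth_dir.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)

    for sid in cohort.samples["sample_id"]:
        eio.write_methylation_table(cohort.methylation[sid], meth_dir / f"{sid}.cpg.bedgraph")
        eio.write_methylation_table(
            cohort.methylation_cpa[sid], meth_dir / f"{sid}.cpa.bedgraph"
        )
    eio.write_sample_sheet(cohort.samples, outdir / "samples.csv")
    eio.write_gene_annotation(cohort.genes, outdir / "genes.bed")
    eio.write_expression_counts(cohort.expression, outdir / "expression.tsv")
    eio.write_table(cohort.truth.sites, truth_dir / "sites.tsv")
    eio.write_table(cohort.truth.genes, truth_dir / "genes.tsv")
    eio.write_table(cohort.truth.attractors, truth_dir / "attractors.tsv")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(cohort.config), fh, sort_keys=True)
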