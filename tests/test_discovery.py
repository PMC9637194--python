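import numpy as np
import pandas as pd
import pytest

from epirelapse import discovery, pipeline, synthetic, trajectory
from epirelapse.errors import ValidationError


def traj_frame(site_states):
    """Build a classified trajectory table from {(chrom,start): states}."""
    rows = []
    for (chrom, start), states in site_states.items():
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "states": tuple(states),
                "category": trajectory.classify_trajectory(states) if states else "Uncovered",
            }
        )
    return pd.DataFrame(rows)


def call_frame(site_dirs, delta=0.6):
    rows = [
        {"chrom": c, "start": s, "direction": d, "delta": delta if d == "Hyper" else (-delta if d == "Hypo" else 0.0)}
        for (c, s), d in site_dirs.items()
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "direction", "delta"])


SITE = ("chr1", 100)


class TestDrivers:
    def test_site_missing_in_one_patient_is_not_a_driver(self):
        consistent = ("Hyper", "Hyper", "Hyper")
        trajs = {
            f"P{i}": traj_frame({SITE: consistent, ("chr1", 500): consistent})
            for i in range(4)
        }
        trajs["P4"] = traj_frame({("chr1", 500): consistent})  # lacks SITE
        deltas = pd.DataFrame(
            {f"s{i}": [0.5, 0.5] for i in range(5)},
            index=pd.MultiIndex.from_tuples([SITE, ("chr1", 500)]),
        )
        out = discovery.find_drivers(trajs, deltas)
        assert list(zip(out["chrom"], out["start"])) == [("chr1", 500)]

    def test_mean_delta_filter_strictness(self):
        trajs = {p: traj_frame({SITE: ("Hyper", "Hyper")}) for p in ("A", "B")}
        at_boundary = pd.DataFrame({"s1": [0.3], "s2": [0.3]}, index=pd.MultiIndex.from_tuples([SITE]))
        assert discovery.find_drivers(trajs, at_boundary).empty
        above = pd.DataFrame({"s1": [0.31], "s2": [0.31]}, index=pd.MultiIndex.from_tuples([SITE]))
        assert len(discovery.find_drivers(trajs, above)) == 1


class TestBoosters:
    def test_persistence_required_at_every_relapse(self):
        trajs = {
            "A": traj_frame(
                {
                    SITE: ("NoChange", "Hyper", "NoChange"),  # lost at R2
                    ("chr1", 300): ("NoChange", "Hyper", "Hyper"),
                }
            ),
            "B": traj_frame(
                {SITE: ("NoChange", "Hyper", "Hyper"), ("chr1", 300): ("NoChange", "Hyper", "Hyper")}
            ),
        }
        out = discovery.find_boosters(trajs)
        assert list(zip(out["chrom"], out["start"])) == [("chr1", 300)]

    def test_patient_without_primary_excluded_with_warning(self):
        trajs = {
            "A": traj_frame({SITE: ("NoChange", "Hyper")}),
            "B": traj_frame({SITE: ("Hyper", "Hyper")}),  # pretend no primary
        }
        with pytest.warns(UserWarning, match="without primary"):
            out = discovery.find_boosters(trajs, has_primary={"A": True, "B": False})
        assert list(zip(out["chrom"], out["start"])) == [SITE]

    def test_driver_booster_disjoint_by_construction(self, tiny_analysis):
        for sub in tiny_analysis["subtypes"].values():
            drivers = set(zip(sub["drivers"]["chrom"], sub["drivers"]["start"]))
            boosters = set(zip(sub["boosters"]["chrom"], sub["boosters"]["start"]))
            assert drivers.isdisjoint(boosters)


class TestPredictors:
    def test_specificity_and_rank_boundary(self):
        rec = {
            "A": call_frame({SITE: "Hyper", ("chr1", 300): "Hyper"}, delta=0.8),
            "B": call_frame({SITE: "Hyper", ("chr1", 300): "Hyper"}, delta=0.8),
        }
        relapse = {
            "A-R1": call_frame({SITE: "Hyper", ("chr1", 300): "Hyper"}),
            "B-R1": call_frame({SITE: "Hyper", ("chr1", 300): "Hyper"}),
        }
        nonrec = [call_frame({("chr1", 300): "Hyper"})]  # 300 also in non-recurrent
        out = discovery.find_predictors(rec, nonrec, relapse)
        assert list(zip(out["chrom"], out["start"])) == [SITE]
        assert bool(out["top"].iloc[0]) is True  # rank exactly 0.80 -> flagged

    def test_below_top_threshold_not_flagged(self):
        rec = {"A": call_frame({SITE: "Hyper"}, delta=0.5)}
        relapse = {"A-R1": call_frame({SITE: "Hyper"})}
        out = discovery.find_predictors(rec, [call_frame({})], relapse)
        assert bool(out["top"].iloc[0]) is False

    def test_missing_nonrecurrent_reference_refused(self):
        rec = {"A": call_frame({SITE: "Hyper"})}
        with pytest.raises(ValidationError, match="non-recurrent"):
            discovery.find_predictors(rec, [], {"A-R1": call_frame({SITE: "Hyper"})})


class TestPlantedRecovery:
    def test_all_planted_kinds_recovered_on_tiny_cohort(self, tiny_cohort, tiny_analysis):
        """Full recall for planted drivers/boosters/predictors with correct
        polarity; every predictor candidate excludes the non-recurrent
        primary's marks by construction."""
        truth = tiny_cohort.truth
        want_dir = truth.sites.set_index(["chrom", "start"])["direction"]
        for kind in ("driver", "booster", "predictor"):
            planted = truth.planted_sites(kind)
            called = set()
            for st in ("RELA", "PFA"):
                df = tiny_analysis["subtypes"][st][f"{kind}s"]
                for r in df.itertuples(index=False):
                    called.add((r.chrom, r.start))
                    if (r.chrom, r.start) in planted:
                        assert r.direction == want_dir[(r.chrom, r.start)]
            assert planted <= called, kind

    def test_predictor_sites_absent_from_driver_truth(self, tiny_cohort, tiny_analysis):
        """Planted drivers are shifted in the non-recurrent primary too, so
        the specificity rule keeps them out of the predictor set."""
        drivers_planted = tiny_cohort.truth.planted_sites("driver")
        for st in ("RELA", "PFA"):
            pre = tiny_analysis["subtypes"][st]["predictors"]
            called = set(zip(pre["chrom"], pre["start"]))
            assert called.isdisjoint(drivers_planted)


class TestPdoxFilter:
    def test_preservation_requires_all_models(self):
        cand = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 200],
             "kind": "driver", "direction": ["Hyper", "Hypo"]}
        )
        ev = {
            "pdox1": {((("chr1", 100)), "Hyper"), (("chr1", 200), "Hypo")},
            "pdox2": {(("chr1", 100), "Hyper")},
        }
        out = discovery.pdox_filter(cand, ev)
        assert list(out["pdox_preserved"]) == ["yes", "no"]

    def test_no_models_means_not_evaluated(self):
        cand = pd.DataFrame({"chrom": ["chr1"], "start": [100], "kind": "driver", "direction": ["Hyper"]})
        out = discovery.pdox_filter(cand, {})
        assert list(out["pdox_preserved"]) == ["not_evaluated"]

    def test_summary_arithmetic(self):
        assert discovery.preservation_percent(479, 529) == 90.5
        assert discovery.preservation_percent(53, 59) == 89.8

    def test_zero_noise_models_preserve_everything(self):
        cfg = synthetic.CohortConfig(
            n_patients_per_subtype=1,
            n_relapses_per_patient={"RELA": (2,), "PFA": (2,)},
            n_sites=1500, n_cpa_sites=50, n_genes=50,
            n_driver_sites=30, n_booster_sites=15, n_predictor_sites=15,
            n_switch_sites=20, mean_coverage=80, pdox_noise_sd=0.0,
            frac_genes_methylation_coupled=0.0, seed=5,
        )
        frac = _driver_preservation_fraction(cfg)
        assert frac == 1.0

    def test_preservation_degrades_with_pdox_noise(self):
        """Mean preservation of planted drivers drops when PDOX noise grows."""
        fracs = {0.05: [], 0.3: []}
        for seed in range(6):
            for sd in fracs:
                cfg = synthetic.CohortConfig(
                    n_patients_per_subtype=1,
                    n_relapses_per_patient={"RELA": (2,), "PFA": (2,)},
                    n_sites=1500, n_cpa_sites=50, n_genes=50,
                    n_driver_sites=30, n_booster_sites=15, n_predictor_sites=15,
                    n_switch_sites=20, mean_coverage=80, pdox_noise_sd=sd,
                    frac_genes_methylation_coupled=0.0, seed=100 + seed,
                )
                fracs[sd].append(_driver_preservation_fraction(cfg))
        assert np.mean(fracs[0.3]) < np.mean(fracs[0.05])


def _driver_preservation_fraction(cfg):
    from epirelapse import dmc

    co = synthetic.simulate_cohort(cfg)
    sheet = co.samples
    truth_dir = co.truth.sites.set_index(["chrom", "start"])["direction"]
    planted = co.truth.planted_sites("driver")
    cand = pd.DataFrame(
        [{"chrom": c, "start": s, "kind": "driver", "direction": truth_dir[(c, s)]} for c, s in sorted(planted)]
    )
    ev = {}
    for row in sheet[sheet["role"] == "pdox"].itertuples(index=False):
        calls = dmc.call_dmcs(
            dmc.filter_coverage(co.methylation[row.sample_id]),
            dmc.filter_coverage(co.methylation[row.matched_normal_id]),
        )
        ev[row.sample_id] = {
            ((r.chrom, r.start), r.direction)
            for r in calls.itertuples(index=False)
            if r.direction != "NoChange"
        }
    out = discovery.pdox_filter(cand, ev)
    return float((out["pdox_preserved"] == "yes").mean())
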