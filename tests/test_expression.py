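import numpy as np
import pandas as pd
import pytest

from epirelapse import expression


def counts_frame(rows, samples):
    return pd.DataFrame(rows, columns=samples)


class TestCallDegs:
    def test_identical_counts_not_deg(self):
        counts = pd.DataFrame(
            {f"t{i}": [50, 100] for i in range(3)} | {f"n{i}": [50, 100] for i in range(3)},
            index=["gA", "gB"],
        )
        out = expression.call_degs(counts, [f"t{i}" for i in range(3)], [f"n{i}" for i in range(3)])
        assert (out["log2_fold_change"] == 0).all()
        assert (~out["is_deg"]).all()
        assert (out["p_value"] == 1.0).all()  # zero-variance groups -> no evidence

    def test_exact_twofold_boundary_is_inclusive(self):
        # gene gX has mean CPM exactly 2x normal (library sizes balanced by gY)
        tumors = [f"t{i}" for i in range(5)]
        normals = [f"n{i}" for i in range(5)]
        gx_t, gx_n = [198, 202, 200, 199, 201], [99, 101, 100, 100, 100]
        counts = pd.DataFrame(
            [gx_t + gx_n, [1000 - v for v in gx_t] + [1000 - v for v in gx_n]],
            index=["gX", "gY"],
            columns=tumors + normals,
        )
        out = expression.call_degs(counts, tumors, normals).set_index("gene_id")
        assert out.loc["gX", "log2_fold_change"] == pytest.approx(1.0, abs=1e-12)
        assert out.loc["gX", "q_value"] <= 0.05
        assert bool(out.loc["gX", "is_deg"])  # >= is inclusive at the boundary

    def test_all_zero_gene_excluded_and_one_sided_zero_handled(self):
        tumors, normals = ["t0", "t1"], ["n0", "n1"]
        counts = pd.DataFrame(
            {"t0": [0, 0, 90], "t1": [0, 0, 110], "n0": [0, 60, 40], "n1": [0, 40, 60]},
            index=["dead", "offT", "ref"],
        )
        out = expression.call_degs(counts, tumors, normals)
        assert "dead" not in set(out["gene_id"])
        off = out.set_index("gene_id").loc["offT"]
        assert np.isneginf(off["log2_fold_change"])

    def test_null_simulation_type_i_control(self):
        """Same NB distribution in both groups: BH-significant fraction <=1%."""
        rng = np.random.default_rng(17)
        mu = rng.lognormal(np.log(100), 1, 2000)
        disp = 20
        draw = lambda: rng.negative_binomial(disp, disp / (disp + mu))
        counts = pd.DataFrame(
            {f"s{i}": draw() for i in range(10)}, index=[f"g{i}" for i in range(2000)]
        )
        out = expression.call_degs(counts, [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)])
        assert (out["q_value"] <= 0.05).mean() <= 0.01

    def test_planted_coupled_genes_recovered(self, tiny_cohort):
        """Methylation-coupled genes are DEGs with the right polarity."""
        co = tiny_cohort
        sheet = co.samples
        tumors = list(
            sheet.loc[(sheet["subtype"] == "RELA") & sheet["role"].isin(["primary", "relapse"]), "sample_id"]
        )
        normals = list(sheet.loc[sheet["role"] == "normal_cerebrum", "sample_id"])
        out = expression.call_degs(co.expression, tumors, normals).set_index("gene_id")
        coupled = co.truth.genes[co.truth.genes["label"] != "unlinked"]
        hits = 0
        for g in coupled.itertuples(index=False):
            rec = out.loc[g.gene_id]
            want_sign = -1 if g.label == "hyper_down" else 1
            if bool(rec["is_deg"]) and np.sign(rec["log2_fold_change"]) == want_sign:
                hits += 1
        assert hits / len(coupled) >= 0.9


class TestIntegrate:
    def _run(self, meth_row, expr_row, direction="Hyper", deg_dir="down"):
        cand = pd.DataFrame({"gene_id": ["g"], "kind": ["driver"], "direction": [direction]})
        degs = pd.DataFrame(
            {
                "gene_id": ["g"],
                "log2_fold_change": [-2.0 if deg_dir == "down" else 2.0],
                "p_value": [1e-6],
                "q_value": [1e-5],
                "is_deg": [True],
            }
        )
        samples = [f"s{i}" for i in range(len(meth_row))]
        meth = pd.DataFrame([meth_row], index=["g"], columns=samples)
        expr = pd.DataFrame([expr_row], index=["g"], columns=samples)
        return expression.integrate(cand, degs, meth, expr).iloc[0]

    def test_perfect_anticorrelation_concordant(self):
        rec = self._run([0.1, 0.5, 0.9], [9, 5, 1])
        assert rec["pearson_r"] == pytest.approx(-1.0)
        assert bool(rec["concordant"])

    def test_direction_mismatch_not_concordant(self):
        rec = self._run([0.1, 0.5, 0.9], [9, 5, 1], direction="Hypo", deg_dir="down")
        assert rec["pearson_r"] == pytest.approx(-1.0)
        assert not rec["concordant"]

    def test_constant_methylation_not_evaluated(self):
        rec = self._run([0.5, 0.5, 0.5], [9, 5, 1])
        assert not rec["evaluated"] and np.isnan(rec["pearson_r"])

    def test_r_matches_covariance_formula(self):
        """Reported r equals the closed-form covariance/sigma formula."""
        rng = np.random.default_rng(9)
        m = rng.uniform(0, 1, 8)
        e = rng.normal(5, 2, 8)
        rec = self._run(m, e)
        manual = ((m - m.mean()) * (e - e.mean())).sum() / np.sqrt(
            ((m - m.mean()) ** 2).sum() * ((e - e.mean()) ** 2).sum()
        )
        assert rec["pearson_r"] == pytest.approx(manual, abs=1e-12)

    def test_concordant_set_shrinks_as_threshold_tightens(self):
        rng = np.random.default_rng(13)
        samples = [f"s{i}" for i in range(10)]
        genes = [f"g{i}" for i in range(30)]
        meth = pd.DataFrame(rng.uniform(0, 1, (30, 10)), index=genes, columns=samples)
        expr = pd.DataFrame(8 - 3 * meth.to_numpy() + rng.normal(0, 2, (30, 10)), index=genes, columns=samples)
        cand = pd.DataFrame({"gene_id": genes, "kind": "driver", "direction": "Hyper"})
        degs = pd.DataFrame(
            {"gene_id": genes, "log2_fold_change": -2.0, "p_value": 1e-6, "q_value": 1e-5, "is_deg": True}
        )
        sizes = [
            int(expression.integrate(cand, degs, meth, expr, max_r=mr)["concordant"].sum())
            for mr in (0.0, -0.3, -0.6, -0.9)
        ]
        assert sizes == sorted(sizes, reverse=True)
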