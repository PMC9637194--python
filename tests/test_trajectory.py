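import itertools
import re

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epirelapse import trajectory
from epirelapse.errors import ValidationError
from tests.test_dmc import make_table
from epirelapse import dmc


def rule_table_oracle(states):
    """Independent regex-based classifier used as the enumeration oracle."""
    s = "".join({"Hyper": "H", "Hypo": "L", "NoChange": "N"}[x] for x in states)
    if "HL" in s or "LH" in s:
        return "ExcludedPolaritySwitch"
    if set(s) == {"N"}:
        return "NoChange"
    x = "H" if "H" in s else "L"
    name = {"H": "Hyper", "L": "Hypo"}[x]
    if re.fullmatch(f"{x}+", s):
        return f"Consistent{name}"
    if re.fullmatch(f"N+{x}+", s):
        return f"Gain{name}"
    if re.fullmatch(f"{x}+N+", s):
        return f"Loss{name}"
    return "Switch"


ALL_CATEGORIES = set(trajectory.CATEGORIES) | {"ExcludedPolaritySwitch", "NoChange"}


class TestClassifier:
    @pytest.mark.parametrize(
        "states,expected",
        [
            (("Hyper",) * 4, "ConsistentHyper"),
            (("NoChange", "Hyper", "Hyper"), "GainHyper"),
            (("Hypo", "NoChange", "NoChange"), "LossHypo"),
            (("NoChange", "Hyper", "NoChange"), "Switch"),
            (("Hyper", "Hypo", "Hyper"), "ExcludedPolaritySwitch"),
            (("NoChange", "NoChange"), "NoChange"),
        ],
    )
    def test_named_category_examples(self, states, expected):
        assert trajectory.classify_trajectory(states) == expected

    def test_exhaustive_oracle_equivalence_up_to_length_five(self):
        """Every sequence of length 2..5 agrees with the rule-table oracle."""
        for length in range(2, 6):
            for states in itertools.product(trajectory.STATES, repeat=length):
                got = trajectory.classify_trajectory(states)
                assert got == rule_table_oracle(states), states
                assert got in ALL_CATEGORIES  # partition: exactly one category

    @given(st.lists(st.sampled_from(trajectory.STATES), min_size=2, max_size=9))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_oracle_agreement_beyond_exhaustive_range(self, states):
        """Sequences longer than the exhaustive sweep still match the oracle."""
        assert trajectory.classify_trajectory(tuple(states)) == rule_table_oracle(states)

    def test_too_short_and_invalid_symbols(self):
        with pytest.raises(ValidationError):
            trajectory.classify_trajectory(("Hyper",))
        with pytest.raises(ValidationError):
            trajectory.classify_trajectory(("Hyper", "Sideways"))


class TestStateSequences:
    def _calls(self, starts_meths):
        return [
            dmc.call_dmcs(make_table(s, m, [40] * len(s)), make_table(s, n, [40] * len(s)))
            for s, m, n in starts_meths
        ]

    def test_site_missing_at_one_timepoint_is_uncovered(self):
        # site 10 only tested at the first timepoint
        t0 = self._calls([([0, 10], [40, 40], [0, 0])])[0]
        t1 = self._calls([([0], [40], [0])])[0]
        out = trajectory.build_state_sequences([t0, t1])
        cat = out.set_index("start")["category"]
        assert cat[0] == "ConsistentHyper"
        assert cat[10] == "Uncovered"

    def test_fewer_than_two_timepoints_rejected(self):
        t0 = self._calls([([0], [40], [0])])[0]
        with pytest.raises(ValidationError):
            trajectory.build_state_sequences([t0])

    def test_planted_drivers_classify_consistent(self, tiny_cohort, tiny_analysis):
        """>=95% of planted driver sites are ConsistentX in every patient."""
        truth = tiny_cohort.truth.sites
        planted = truth[truth["label"].str.startswith("driver")]
        want = {
            (c, s): f"Consistent{d}"
            for c, s, d in zip(planted["chrom"], planted["start"], planted["direction"])
        }
        for pid, traj in tiny_analysis["trajectories"].items():
            got = traj.set_index(["chrom", "start"])["category"]
            hits = sum(got.get(site) == cat for site, cat in want.items())
            assert hits / len(want) >= 0.95, pid

    def test_planted_boosters_classify_gain(self, tiny_cohort, tiny_analysis):
        truth = tiny_cohort.truth.sites
        planted = truth[truth["label"].str.startswith("booster")]
        want = {
            (c, s): f"Gain{d}"
            for c, s, d in zip(planted["chrom"], planted["start"], planted["direction"])
        }
        for pid, traj in tiny_analysis["trajectories"].items():
            got = traj.set_index(["chrom", "start"])["category"]
            hits = sum(got.get(site) == cat for site, cat in want.items())
            assert hits / len(want) >= 0.95, pid


class TestFractionsAndFlows:
    def test_two_category_example(self):
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": range(20),
                "states": [("Hyper", "Hyper")] * 20,
                "category": ["ConsistentHyper"] * 10 + ["Switch"] * 10,
            }
        )
        fr = trajectory.category_fractions(df)
        assert fr["ConsistentHyper"] == 0.5 and fr["Switch"] == 0.5
        assert fr.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_classified_set(self):
        df = pd.DataFrame(
            {"chrom": [], "start": [], "states": [], "category": []}
        )
        assert trajectory.category_fractions(df).empty

    def test_polarity_switch_fraction_small_when_none_planted(self, tiny_analysis):
        """The generator plants no hyper<->hypo flips, so the excluded
        fraction comes only from sampling noise and stays tiny."""
        for pid, traj in tiny_analysis["trajectories"].items():
            fr = trajectory.category_fractions(traj)
            assert fr.get("ExcludedPolaritySwitch", 0.0) < 0.02, pid

    def test_flow_counts_sum_to_covered_sites(self):
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": range(3),
                "states": [("Hyper", "NoChange"), ("Hyper", "Hyper"), ()],
                "category": ["LossHyper", "ConsistentHyper", "Uncovered"],
            }
        )
        flows = trajectory.state_flow_counts(df)
        assert flows["count"].sum() == 2  # one transition per covered site
        assert set(flows["step"]) == {0}
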