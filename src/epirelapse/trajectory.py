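"""Seven-way classification of longitudinal methylation trajectories.

Within one patient, every CpG tested against the same normal reference at
every available timepoint (primary first, then relapses in order) yields an
ordered state sequence over {Hyper, Hypo, NoChange}.  Sequences are sorted
into the seven dynamic categories used for serially relapsing tumors:

* ``ConsistentHyper`` / ``ConsistentHypo`` — the same polarity at every stage;
* ``GainHyper`` / ``GainHypo`` — a clean NoChange prefix followed by an
  all-Hyper/Hypo suffix (methylation change acquired once and kept);
* ``LossHyper`` / ``LossHypo`` — the mirror image (present early, then lost);
* ``Switch`` — any other mix of one polarity and NoChange (more than one
  toggle, or a gain-then-loss compound).

Sequences containing a direct Hyper<->Hypo flip between adjacent stages are
excluded from the seven categories (``ExcludedPolaritySwitch``): such sites
are rare (<2% in serial-relapse cohorts) and their polarity is unreliable.
All-NoChange sequences are not DMCs and are reported as ``NoChange``; sites
failing coverage at any timepoint are ``Uncovered``.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError

STATES = ("Hyper", "Hypo", "NoChange")

CATEGORIES = (
    "ConsistentHyper",
    "ConsistentHypo",
    "GainHyper",
    "GainHypo",
    "LossHyper",
    "LossHypo",
    "Switch",
)


def classify_trajectory(states: Sequence[str]) -> str:
    """Classify one ordered state sequence (length >= 2)."""
    if len(states) < 2:
        raise ValidationError("classification needs at least two timepoints")
    for s in states:
        if s not in STATES:
            raise ValidationError(f"invalid state symbol {s!r}")

    for left, right in zip(states, states[1:]):
        if {left, right} == {"Hyper", "Hypo"}:
            return "ExcludedPolaritySwitch"

    polar = {s for s in states if s != "NoChange"}
    if not polar:
        return "NoChange"
    if len(polar) == 2:
        # both polarities present but never adjacent (e.g. Hyper,NoChange,Hypo):
        # not excludable, but no clean single-polarity pattern either
        return "Switch"
    x = polar.pop()

    flags = [s == x for s in states]
    if all(flags):
        return f"Consistent{x}"
    n_toggles = sum(a != b for a, b in zip(flags, flags[1:]))
    if n_toggles == 1:
        return f"Gain{x}" if flags[-1] else f"Loss{x}"
    return "Switch"


def build_state_sequences(
    calls_by_timepoint: Sequence[pd.DataFrame],
    classify: bool = True,
) -> pd.DataFrame:
    """Assemble per-site state sequences from per-timepoint DMC calls.

    ``calls_by_timepoint`` holds the DMC call tables of one patient's tumor
    samples against the *same* normal reference, ordered by timepoint
    (primary first if present).  A site appears in a call table only if it
    passed coverage in both tumor and normal, so any site missing from some
    timepoint is ``Uncovered``.

    Returns a frame ``[chrom, start, states, category]`` where ``states`` is
    a tuple per site (empty for uncovered sites).
    """
    if len(calls_by_timepoint) < 2:
        raise ValidationError("trajectory classification needs >= 2 timepoints")

    cols = []
    for i, calls in enumerate(calls_by_timepoint):
        s = calls.set_index(["chrom", "start"])["direction"]
        s.name = i
        cols.append(s)
    wide = pd.concat(cols, axis=1, join="outer")

    covered = wide.notna().all(axis=1)
    states = [tuple(row) if ok else () for row, ok in zip(wide.to_numpy(), covered)]
    out = wide.index.to_frame(index=False)
    out["states"] = states

    if classify:
        cache: dict[tuple, str] = {}

        def _cat(seq: tuple) -> str:
            if not seq:
                return "Uncovered"
            if seq not in cache:
                cache[seq] = classify_trajectory(seq)
            return cache[seq]

        out["category"] = [_cat(seq) for seq in states]
    return out


def category_fractions(trajectories: pd.DataFrame) -> pd.Series:
    """Fraction of classified DMC sites per category (sums to 1).

    Uncovered sites and all-NoChange sequences are not DMCs and are excluded
    from the denominator; the polarity-switch exclusion is reported as its
    own fraction so its (small) share is visible.
    """
    cats = trajectories["category"]
    cats = cats[~cats.isin(["Uncovered", "NoChange"])]
    if cats.empty:
        return pd.Series(dtype=float)
    return cats.value_counts(normalize=True).sort_index()


def state_flow_counts(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Alluvial-ready transition counts between adjacent timepoints.

    Returns ``[step, state_from, state_to, count]`` where ``step`` is the
    index of the (from, to) adjacent-timepoint pair, counted over sites
    covered at all timepoints.
    """
    rows = []
    for seq in trajectories.loc[trajectories["category"] != "Uncovered", "states"]:
        for step, (a, b) in enumerate(zip(seq, seq[1:])):
            rows.append((step, a, b))
    if not rows:
        return pd.DataFrame(columns=["step", "state_from", "state_to", "count"])
    flows = pd.DataFrame(rows, columns=["step", "state_from", "state_to"])
    out = (
        flows.value_counts(["step", "state_from", "state_to"])
        .rename("count")
        .reset_index()
        .sort_values(["step", "state_from", "state_to"])
        .reset_index(drop=True)
    )
    return out


def consistent_site_sets(trajectories: pd.DataFrame) -> Mapping[str, set]:
    """Sites classified ConsistentHyper / ConsistentHypo, keyed by polarity."""
    out = {}
    for direction in ("Hyper", "Hypo"):
        mask = trajectories["category"] == f"Consistent{direction}"
        out[direction] = set(
            zip(trajectories.loc[mask, "chrom"], trajectories.loc[mask, "start"])
        )
    return out
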