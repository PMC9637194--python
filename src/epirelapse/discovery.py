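"""Discovery of relapse driver, booster and predictor methylation marks.

Three longitudinal discovery procedures over a subtype's patients, all
operating on per-patient trajectory tables and per-sample DMC calls made
against the same normal references:

* **drivers** — sites consistently Hyper (or Hypo) from the primary through
  every relapse of *every* patient, further restricted to a mean
  tumor-normal ratio difference > ``delta_min`` (default 0.3): abnormal
  methylation already present at diagnosis and sustained through relapse.
* **boosters** — sites NoChange in every primary but Hyper/Hypo at *every*
  relapse of every patient: methylation newly acquired at relapse that
  persists with progression.
* **predictors** — sites that are DMCs in every eventually-recurring
  patient's primary, absent from the non-recurrent reference primary, and
  DMCs with the same polarity in every recurrent sample; ranked by the mean
  |delta| across the recurring primaries, with the top flag at >= 0.8.

The PDOX-preservation filter keeps candidates whose mark is reproduced
(same key, same polarity) in every matched patient-derived orthotopic
xenograft, the in-vivo check that a candidate survives engraftment.
"""

from __future__ import annotations

import math
import warnings
from typing import Hashable, Iterable, Mapping, Sequence

import pandas as pd

from .cohort_sets import apply_consistency_delta
from .errors import ValidationError

CANDIDATE_COLUMNS = ["chrom", "start", "kind", "direction", "mean_delta", "supporting_patients"]


def _sites_by_direction(traj: pd.DataFrame, predicate) -> dict[str, set]:
    out = {"Hyper": set(), "Hypo": set()}
    for row in traj.itertuples(index=False):
        if not row.states:
            continue
        for direction in ("Hyper", "Hypo"):
            if predicate(row.states, direction):
                out[direction].add((row.chrom, row.start))
    return out


def find_drivers(
    trajectories: Mapping[str, pd.DataFrame],
    deltas: pd.DataFrame,
    delta_min: float = 0.3,
) -> pd.DataFrame:
    """Consistent-in-all-patients DMCs passing the mean-delta filter.

    ``trajectories`` maps patient -> classified trajectory table;
    ``deltas`` is the sites x tumor-samples delta matrix of the subtype
    (every tumor sample, used by the consistency filter).
    """
    patients = sorted(trajectories)
    if len(patients) < 2:
        warnings.warn("driver discovery with <2 patients: single-patient passthrough")

    rows = []
    for direction in ("Hyper", "Hypo"):
        per_patient = [
            {
                (r.chrom, r.start)
                for r in trajectories[p].itertuples(index=False)
                if r.category == f"Consistent{direction}"
            }
            for p in patients
        ]
        shared = set.intersection(*per_patient) if per_patient else set()
        kept, _ = apply_consistency_delta(shared, deltas, delta_min=delta_min)
        for chrom, start in kept:
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "kind": "driver",
                    "direction": direction,
                    "mean_delta": float(deltas.loc[(chrom, start)].mean()),
                    "supporting_patients": ",".join(patients),
                }
            )
    return _finish(rows)


def find_boosters(
    trajectories: Mapping[str, pd.DataFrame],
    has_primary: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Relapse-acquired, relapse-persistent DMCs absent from every primary.

    A site qualifies in one patient when its primary state is NoChange and
    every relapse state is the same polarity.  Patients without a primary
    sample cannot certify "absent in primary" and are excluded from support
    (with a warning).
    """
    has_primary = has_primary or {p: True for p in trajectories}
    usable = [p for p in sorted(trajectories) if has_primary.get(p, False)]
    skipped = sorted(set(trajectories) - set(usable))
    if skipped:
        warnings.warn(f"patients without primary excluded from booster support: {skipped}")
    if not usable:
        raise ValidationError("no patient with a primary sample; boosters undefined")

    def booster_pred(states: Sequence[str], direction: str) -> bool:
        return (
            len(states) >= 2
            and states[0] == "NoChange"
            and all(s == direction for s in states[1:])
        )

    rows = []
    for direction in ("Hyper", "Hypo"):
        per_patient = [
            _sites_by_direction(trajectories[p], booster_pred)[direction] for p in usable
        ]
        shared = set.intersection(*per_patient) if per_patient else set()
        for chrom, start in shared:
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "kind": "booster",
                    "direction": direction,
                    "mean_delta": math.nan,
                    "supporting_patients": ",".join(usable),
                }
            )
    return _finish(rows)


def find_predictors(
    recurring_primary_calls: Mapping[str, pd.DataFrame],
    nonrecurrent_primary_calls: Sequence[pd.DataFrame],
    relapse_calls: Mapping[str, pd.DataFrame],
    delta_top: float = 0.8,
) -> pd.DataFrame:
    """Primary-tumor DMCs that forecast relapse.

    A candidate is a same-direction DMC in *every* recurring patient's
    primary, not a DMC (either direction) in *any* non-recurrent reference
    primary, and a same-direction DMC in *every* recurrent sample.
    ``rank_score`` is the mean |delta| over the recurring primaries;
    candidates with rank_score >= ``delta_top`` carry the ``top`` flag.
    """
    if not nonrecurrent_primary_calls:
        raise ValidationError(
            "a non-recurrent reference primary is required to establish specificity"
        )
    if not recurring_primary_calls or not relapse_calls:
        raise ValidationError("need recurring primary and relapse DMC sets")

    def dmc_sites(calls: pd.DataFrame, direction: str) -> set:
        mask = calls["direction"] == direction
        return set(zip(calls.loc[mask, "chrom"], calls.loc[mask, "start"]))

    excluded: set = set()
    for calls in nonrecurrent_primary_calls:
        mask = calls["direction"] != "NoChange"
        excluded |= set(zip(calls.loc[mask, "chrom"], calls.loc[mask, "start"]))

    patients = sorted(recurring_primary_calls)
    rows = []
    for direction in ("Hyper", "Hypo"):
        shared = set.intersection(
            *[dmc_sites(recurring_primary_calls[p], direction) for p in patients]
        )
        for sample in sorted(relapse_calls):
            shared &= dmc_sites(relapse_calls[sample], direction)
            if not shared:
                break
        shared -= excluded
        if not shared:
            continue
        delta_by_patient = [
            recurring_primary_calls[p].set_index(["chrom", "start"])["delta"] for p in patients
        ]
        for site in shared:
            score = float(pd.Series([d.loc[site] for d in delta_by_patient]).abs().mean())
            rows.append(
                {
                    "chrom": site[0],
                    "start": site[1],
                    "kind": "predictor",
                    "direction": direction,
                    "mean_delta": score,
                    "supporting_patients": ",".join(patients),
                    "rank_score": score,
                    "top": score >= delta_top,
                }
            )
    out = _finish(rows)
    if "rank_score" in out.columns:
        out = out.sort_values("rank_score", ascending=False, kind="stable").reset_index(drop=True)
    else:
        out["rank_score"] = pd.Series(dtype=float)
        out["top"] = pd.Series(dtype=bool)
    return out


def _finish(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)
    out = pd.DataFrame(rows)
    return out.sort_values(["chrom", "start", "direction"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# PDOX preservation
# ---------------------------------------------------------------------------

def pdox_filter(
    candidates: pd.DataFrame,
    pdox_evidence: Mapping[str, Iterable[tuple[Hashable, str]]],
    key_columns: Sequence[str] = ("chrom", "start"),
) -> pd.DataFrame:
    """Flag candidates preserved in every matched PDOX model.

    ``pdox_evidence`` maps a PDOX sample id to the set of ``(key, direction)``
    marks called in that model (site keys for DMC-level candidates, gene ids
    for DMR-associated gene candidates).  A candidate is ``preserved`` iff
    every given PDOX sample carries its key with the same polarity;
    with no PDOX samples the flag is ``not_evaluated``.
    """
    out = candidates.copy()
    sets = [frozenset(marks) for _, marks in sorted(pdox_evidence.items())]
    if not sets:
        out["pdox_preserved"] = "not_evaluated"
        return out

    def status(row) -> str:
        key = tuple(row[c] for c in key_columns)
        if len(key) == 1:
            key = key[0]
        mark = (key, row["direction"])
        return "yes" if all(mark in s for s in sets) else "no"

    out["pdox_preserved"] = out.apply(status, axis=1) if len(out) else pd.Series(dtype=str)
    return out


def preservation_percent(preserved: int, total: int) -> float:
    """``100 * preserved / total`` rounded half-up to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return math.floor(1000.0 * preserved / total + 0.5) / 10.0


def preservation_summary(candidates: pd.DataFrame) -> pd.DataFrame:
    """Preserved/total/percent per (kind, direction) over evaluated candidates."""
    rows = []
    evaluated = candidates[candidates.get("pdox_preserved", pd.Series(dtype=str)) != "not_evaluated"]
    for (kind, direction), grp in evaluated.groupby(["kind", "direction"], sort=True):
        total = len(grp)
        preserved = int((grp["pdox_preserved"] == "yes").sum())
        rows.append(
            {
                "kind": kind,
                "direction": direction,
                "preserved": preserved,
                "total": total,
                "percent": preservation_percent(preserved, total),
            }
        )
    return pd.DataFrame(rows, columns=["kind", "direction", "preserved", "total", "percent"])
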