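"""Cross-patient set logic for shared DMC discovery.

Per-patient consistent-DMC site sets are intersected across all patients of
a molecular subtype ("shared by all"), and an UpSet-style tally reports, for
every nonempty patient combination, the number of sites present in exactly
that combination of patients (exclusive-intersection semantics).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

import pandas as pd


@dataclass
class SharedDmcSet:
    """Sites shared by every patient of one subtype, with evidence."""

    subtype: str
    direction: str
    sites: frozenset
    #: per-site number of patients carrying it (== n patients for members)
    support: dict = field(default_factory=dict)
    #: patients x sites boolean presence matrix
    membership: pd.DataFrame | None = None


def intersect_patients(
    sets_by_patient: Mapping[str, Iterable[Hashable]],
    subtype: str = "",
    direction: str = "",
) -> tuple[SharedDmcSet, pd.DataFrame]:
    """Exact all-patient intersection plus UpSet exclusive tallies.

    Returns the :class:`SharedDmcSet` and a tally frame
    ``[patients, n_patients, count]`` where ``patients`` is the
    '+'-joined sorted patient combination and ``count`` the number of sites
    found in exactly those patients.
    """
    if len(sets_by_patient) < 2:
        raise ValueError("need sets from at least two patients")
    patients = sorted(sets_by_patient)
    sets = {p: set(sets_by_patient[p]) for p in patients}

    shared = set.intersection(*sets.values())
    support: Counter = Counter()
    combo_of_site: dict[Hashable, tuple] = {}
    for p in patients:
        for site in sets[p]:
            support[site] += 1
            combo_of_site.setdefault(site, ())
    for site in combo_of_site:
        combo_of_site[site] = tuple(p for p in patients if site in sets[p])

    tally = Counter(combo_of_site.values())
    tally_df = pd.DataFrame(
        [("+".join(combo), len(combo), count) for combo, count in sorted(tally.items())],
        columns=["patients", "n_patients", "count"],
    )

    union = sorted(combo_of_site, key=repr)
    membership = pd.DataFrame(
        [[site in sets[p] for site in union] for p in patients],
        index=pd.Index(patients, name="patient"),
        columns=union,
    )
    result = SharedDmcSet(
        subtype=subtype,
        direction=direction,
        sites=frozenset(shared),
        support={s: support[s] for s in shared},
        membership=membership,
    )
    return result, tally_df


def apply_consistency_delta(
    sites: Iterable[Hashable],
    deltas: pd.DataFrame,
    delta_min: float = 0.3,
    per_sample: bool = False,
) -> tuple[set, int]:
    """Keep sites with a large, direction-uniform methylation difference.

    ``deltas`` is a sites x tumor-samples frame of per-sample ratio
    differences (tumor − normal) for every tumor of the subtype.  A site is
    retained when every sample's delta has the same sign and the mean
    ``|delta|`` strictly exceeds ``delta_min`` (with ``per_sample=True``
    every individual ``|delta|`` must exceed it).  Sites with a missing
    delta in any sample are dropped; the second return value counts them.
    """
    kept: set = set()
    n_dropped_missing = 0
    for site in sites:
        if site not in deltas.index:
            n_dropped_missing += 1
            continue
        row = deltas.loc[site]
        vals = row.to_numpy(dtype=float)
        if pd.isna(vals).any():
            n_dropped_missing += 1
            continue
        uniform = (vals > 0).all() or (vals < 0).all()
        if not uniform:
            continue
        if per_sample:
            ok = (abs(vals) > delta_min).all()
        else:
            ok = abs(vals.mean()) > delta_min
        if ok:
            kept.add(site)
    return kept, n_dropped_missing
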