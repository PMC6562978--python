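"""Demographic composition of groups and zone-level means.

Each group's composition is the proportion of its members in each of the
six size/maturity classes.  Note the denominator deliberately differs from
group size: composition counts every member *including* pouch young,
whereas group size excludes them.  Zone-level means are unweighted: first
averaged over groups within a session, then over sessions, with the
standard error taken across sessions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .landscape import DEMO_CLASSES


def group_composition(group: pd.DataFrame) -> pd.Series:
    """Proportions of the six demographic classes within one group.

    The denominator is the total membership including in-pouch young.
    Returns a series indexed by class, summing to 1.
    """
    if group.empty:
        raise ValueError("group is empty")
    counts = group["demo_class"].value_counts()
    props = pd.Series(
        [counts.get(c, 0) / len(group) for c in DEMO_CLASSES],
        index=list(DEMO_CLASSES),
        dtype=float,
    )
    return props


def composition_table(partition, weighted: bool = False) -> pd.DataFrame:
    """Per-group composition rows for one partition.

    Each row: session, zone, group_id, total members, and one proportion
    column per class.  ``weighted`` is carried through to
    :func:`mean_composition` consumers as metadata only; per-group rows are
    identical either way.
    """
    rows = []
    for gid, g in partition.groups():
        props = group_composition(g)
        rows.append(
            {
                "session": g["session"].iloc[0] if "session" in g else None,
                "zone": g["zone"].iloc[0] if "zone" in g else None,
                "group_id": gid,
                "n_members": len(g),
                **props.to_dict(),
            }
        )
    return pd.DataFrame(rows)


def mean_composition(
    compositions: pd.DataFrame, weighted: bool = False
) -> pd.DataFrame:
    """Zone-level mean composition with standard errors.

    Per-group proportions are averaged over groups within each session
    (unweighted by group size unless ``weighted``), then over sessions;
    the SE is the standard error of the session means.  Zones with no
    groups are simply absent.

    Expects the output of :func:`composition_table` (possibly concatenated
    over chain distances, with a ``chain_m`` column).
    """
    if compositions.empty:
        raise ValueError("no composition rows supplied")
    keys = ["zone"]
    if "chain_m" in compositions.columns:
        keys = ["zone", "chain_m"]

    rows = []
    for key, sub in compositions.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        session_means = []
        for _, sess in sub.groupby("session"):
            if weighted:
                w = sess["n_members"].to_numpy(float)
                m = [
                    float(np.average(sess[c], weights=w)) for c in DEMO_CLASSES
                ]
            else:
                m = [float(sess[c].mean()) for c in DEMO_CLASSES]
            session_means.append(m)
        session_means = np.asarray(session_means)
        mean = session_means.mean(axis=0)
        if len(session_means) > 1:
            se = session_means.std(axis=0, ddof=1) / np.sqrt(len(session_means))
        else:
            se = np.full(len(DEMO_CLASSES), np.nan)
        row = dict(zip(keys, key))
        row["n_sessions"] = len(session_means)
        for i, c in enumerate(DEMO_CLASSES):
            row[f"mean_{c}"] = mean[i]
            row[f"se_{c}"] = se[i]
        rows.append(row)
    return pd.DataFrame(rows)
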