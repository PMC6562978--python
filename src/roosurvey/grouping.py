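"""Chain-rule group assignment and per-group spatial metrics.

Group membership follows the "chain-rule": two individuals belong to the
same group if they are within a threshold distance of each other, taken to
transitive closure.  Equivalently, groups are the connected components of
the graph linking all pairs at Euclidean distance <= the chain distance
(single-linkage clustering cut at a fixed height).  Conventional thresholds
for eastern grey kangaroos are 15, 30 and 50 m.

Pouch young ride in their mother's pouch: they are excluded from the point
set used for chaining (and from group size, centroids and spacing) but are
carried into their mother's group for demographic composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

CHAIN_DISTANCES_M = (15.0, 30.0, 50.0)


@dataclass
class Partition:
    """Chain-rule partition of one session's individuals.

    ``membership`` has one row per individual (including in-pouch young,
    which inherit their mother's group) with a ``group_id`` column.  Group
    ids are assigned in order of each group's minimum member id, so the
    labelling is deterministic and independent of input order.
    """

    chain_distance: float
    membership: pd.DataFrame
    _groups: dict[int, pd.DataFrame] = field(default_factory=dict, repr=False)

    @property
    def group_ids(self) -> list[int]:
        return sorted(self._groups)

    @property
    def n_groups(self) -> int:
        return len(self._groups)

    def group(self, group_id: int) -> pd.DataFrame:
        return self._groups[group_id]

    def groups(self):
        """Iterate (group_id, member frame) pairs."""
        for gid in self.group_ids:
            yield gid, self._groups[gid]

    def summary(self) -> pd.DataFrame:
        """Per-group size, centroid and clusteredness table.

        Clusteredness (mean nearest-neighbour distance) is NaN for
        singleton groups, which have no neighbours.
        """
        rows = []
        for gid, g in self.groups():
            cx, cy = group_centroid(g)
            size = group_size(g)
            rows.append(
                {
                    "group_id": gid,
                    "size": size,
                    "cx": cx,
                    "cy": cy,
                    "mean_nn_m": group_clusteredness(g) if size > 1 else np.nan,
                    "zone": g["zone"].iloc[0] if "zone" in g else None,
                    "session": g["session"].iloc[0] if "session" in g else None,
                }
            )
        cols = ["group_id", "size", "cx", "cy", "mean_nn_m", "zone", "session"]
        return pd.DataFrame(rows, columns=cols)


def assign_groups(individuals: pd.DataFrame, chain_distance: float) -> Partition:
    """Partition one session's individuals into chain-rule groups.

    Individuals flagged in-pouch are excluded from the chaining point set
    and afterwards attached to the group of the nearest out-of-pouch
    individual (their mother, with whom they share coordinates).

    Raises ``ValueError`` on a non-positive chain distance or duplicate
    ids; an empty input yields an empty partition.
    """
    if chain_distance <= 0:
        raise ValueError("chain_distance must be positive")
    df = individuals.copy()
    if "id" not in df.columns:
        df["id"] = np.arange(len(df))
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate individual ids: {dupes}")
    if "in_pouch" not in df.columns:
        df["in_pouch"] = 0

    free = df[df["in_pouch"] != 1].reset_index(drop=True)
    pouch = df[df["in_pouch"] == 1].reset_index(drop=True)

    if free.empty:
        membership = df.iloc[0:0].assign(group_id=pd.Series(dtype=int))
        return Partition(chain_distance=chain_distance, membership=membership)

    xy = free[["x_m", "y_m"]].to_numpy(float)
    labels = _chain_components(xy, chain_distance)

    # stable relabelling: order components by their minimum member id
    free = free.assign(_comp=labels)
    order = (
        free.groupby("_comp")["id"].min().sort_values().index.to_numpy()
    )
    remap = {comp: gid for gid, comp in enumerate(order)}
    free["group_id"] = free["_comp"].map(remap)
    free = free.drop(columns="_comp")

    if not pouch.empty:
        tree = cKDTree(xy)
        _, nearest = tree.query(pouch[["x_m", "y_m"]].to_numpy(float))
        pouch = pouch.assign(group_id=free["group_id"].to_numpy()[nearest])

    membership = pd.concat([free, pouch], ignore_index=True)
    membership = membership.sort_values(["group_id", "id"]).reset_index(drop=True)
    groups = {int(gid): g.reset_index(drop=True)
              for gid, g in membership.groupby("group_id")}
    return Partition(
        chain_distance=chain_distance, membership=membership, _groups=groups
    )


def _chain_components(xy: np.ndarray, chain_distance: float) -> np.ndarray:
    """Connected components of the <=-threshold adjacency graph.

    The threshold is closed: pairs at exactly the chain distance are linked.
    """
    n = len(xy)
    pairs = cKDTree(xy).query_pairs(r=chain_distance, output_type="ndarray")
    if len(pairs) == 0:
        return np.arange(n)
    row = np.concatenate([pairs[:, 0], pairs[:, 1]])
    col = np.concatenate([pairs[:, 1], pairs[:, 0]])
    adj = coo_matrix((np.ones(len(row)), (row, col)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def group_size(group: pd.DataFrame, include_out_of_pouch: bool = True) -> int:
    """Number of individuals in a group, excluding in-pouch young.

    Young out of the pouch (young-at-foot) count; set
    ``include_out_of_pouch=False`` to drop them too.
    """
    if group.empty:
        raise ValueError("group is empty")
    in_pouch = group["in_pouch"] == 1 if "in_pouch" in group else pd.Series(False, index=group.index)
    counted = group[~in_pouch]
    if not include_out_of_pouch and "demo_class" in counted:
        counted = counted[counted["demo_class"] != "YAF"]
    return int(len(counted))


def _out_of_pouch_xy(group: pd.DataFrame) -> np.ndarray:
    g = group
    if "in_pouch" in g.columns:
        g = g[g["in_pouch"] != 1]
    return g[["x_m", "y_m"]].to_numpy(float)


def group_centroid(group: pd.DataFrame) -> tuple[float, float]:
    """Geometric centre (coordinate-wise mean) over out-of-pouch members."""
    xy = _out_of_pouch_xy(group)
    if len(xy) == 0:
        raise ValueError("group has no out-of-pouch members")
    return float(xy[:, 0].mean()), float(xy[:, 1].mean())


def group_clusteredness(group: pd.DataFrame) -> float:
    """Mean nearest-neighbour distance (m) among out-of-pouch members.

    Defined only for groups of size > 1; singletons raise ``ValueError``
    (they are excluded upstream when clusteredness is analysed).
    """
    xy = _out_of_pouch_xy(group)
    if len(xy) < 2:
        raise ValueError("clusteredness undefined for singleton groups")
    d, _ = cKDTree(xy).query(xy, k=2)
    return float(d[:, 1].mean())
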