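"""Core containers: per-subject time-series panels and macroscale group schemes.

A *panel* is one subject's node x time matrix of regional signals (e.g. ROI-mean
fMRI time courses).  A *group scheme* assigns every node to exactly one
macroscale group; the reference scheme used throughout is hemisphere x lobe
(2 x 10 = 20 groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The ten macroscale lobes of the reference grouping, in canonical order.
LOBES = (
    "prefrontal",
    "motor",
    "insula",
    "parietal",
    "temporal",
    "occipital",
    "limbic",
    "cerebellum",
    "subcortical",
    "brainstem",
)

HEMISPHERES = ("L", "R")


def default_group_ids() -> list[str]:
    """The 20 hemisphere x lobe group labels in canonical order."""
    return [f"{h}_{lobe}" for h in HEMISPHERES for lobe in LOBES]


@dataclass
class TimeSeriesPanel:
    """One subject's node x time real-valued matrix.

    Parameters
    ----------
    subject_id : str
        Identifier carried through to behavior alignment.
    data : ndarray of shape (n_nodes, n_timepoints)
        Regional time courses, one row per node.
    node_ids : list of str
        Unique node labels aligned with the rows of ``data``.
    condition : {"task", "rest", "other"}
        Acquisition condition label.
    """

    subject_id: str
    data: np.ndarray
    node_ids: list[str]
    condition: str = "other"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("panel data must be a 2-D node x time matrix")
        if self.data.shape[0] < 2:
            raise ValueError("a panel needs at least 2 nodes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("panel data contains non-finite values")
        self.node_ids = [str(n) for n in self.node_ids]
        if len(self.node_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.node_ids)} node ids for {self.data.shape[0]} rows"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            dupes = sorted({n for n in self.node_ids if self.node_ids.count(n) > 1})
            raise ValueError(f"duplicate node ids: {dupes}")
        if self.condition not in ("task", "rest", "other"):
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def series(self, node_id: str) -> np.ndarray:
        return self.data[self.node_ids.index(node_id)]


@dataclass
class GroupScheme:
    """Assignment of each node to exactly one macroscale group.

    ``group_ids`` is kept in a canonical (lexicographically sorted) order so
    that schemes read from differently ordered files compare equal.
    """

    node_to_group: dict[str, str]
    group_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.node_to_group = {str(k): str(v) for k, v in self.node_to_group.items()}
        seen = sorted(set(self.node_to_group.values()))
        if not self.group_ids:
            self.group_ids = seen
        else:
            self.group_ids = sorted(str(g) for g in self.group_ids)
            missing = set(seen) - set(self.group_ids)
            if missing:
                raise ValueError(f"nodes mapped to undeclared groups: {sorted(missing)}")
            empty = set(self.group_ids) - set(seen)
            if empty:
                raise ValueError(f"empty groups: {sorted(empty)}")

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    def group_of(self, node_id: str) -> str:
        try:
            return self.node_to_group[node_id]
        except KeyError:
            raise KeyError(f"node {node_id!r} absent from group scheme") from None

    def nodes_in(self, group_id: str) -> list[str]:
        return [n for n, g in self.node_to_group.items() if g == group_id]

    def check_covers(self, node_ids) -> None:
        missing = [n for n in node_ids if n not in self.node_to_group]
        if missing:
            raise KeyError(f"nodes not covered by scheme: {missing}")

    def group_index(self, node_id: str) -> int:
        return self.group_ids.index(self.group_of(node_id))

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "GroupScheme":
        """Build a scheme from a (node_id, hemisphere, lobe) table.

        Group ids are formed as ``"{hemisphere}_{lobe}"``.
        """
        required = {"node_id", "hemisphere", "lobe"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"scheme table missing columns: {sorted(missing)}")
        node_ids = table["node_id"].astype(str)
        if node_ids.duplicated().any():
            dupes = sorted(node_ids[node_ids.duplicated()].unique())
            raise ValueError(f"node mapped more than once: {dupes}")
        if table[["hemisphere", "lobe"]].isna().any().any():
            bad = table.loc[table[["hemisphere", "lobe"]].isna().any(axis=1), "node_id"]
            raise ValueError(f"missing hemisphere/lobe entry for nodes: {list(bad)}")
        mapping = {
            str(n): f"{h}_{l}"
            for n, h, l in zip(node_ids, table["hemisphere"], table["lobe"])
        }
        return cls(node_to_group=mapping)

    @classmethod
    def contiguous(cls, node_ids, n_groups: int, prefix: str = "g") -> "GroupScheme":
        """Split ``node_ids`` into ``n_groups`` contiguous, near-equal groups.

        Convenience constructor for synthetic cohorts.
        """
        node_ids = [str(n) for n in node_ids]
        if n_groups < 1 or n_groups > len(node_ids):
            raise ValueError("n_groups must be in [1, n_nodes]")
        bounds = np.linspace(0, len(node_ids), n_groups + 1).astype(int)
        width = len(str(n_groups - 1))
        mapping = {}
        for g in range(n_groups):
            for n in node_ids[bounds[g] : bounds[g + 1]]:
                mapping[n] = f"{prefix}{g:0{width}d}"
        return cls(node_to_group=mapping)


def parcellate(
    voxel_matrix: np.ndarray,
    labels,
    node_ids=None,
    subject_id: str = "parcellated",
    condition: str = "other",
) -> TimeSeriesPanel:
    """Average voxel time courses into node time courses.

    Each node's time course is the unweighted mean over its constituent
    voxels at every timepoint; output rows follow sorted node ids.

    Parameters
    ----------
    voxel_matrix : ndarray of shape (n_voxels, n_timepoints)
    labels : sequence of str, length n_voxels
        Node assignment of each voxel row.
    node_ids : sequence of str, optional
        Declared node set.  Any declared node with zero voxels is an error.
    """
    voxel_matrix = np.asarray(voxel_matrix, dtype=float)
    if voxel_matrix.ndim != 2:
        raise ValueError("voxel matrix must be 2-D voxel x time")
    labels = [str(l) for l in labels]
    if len(labels) != voxel_matrix.shape[0]:
        raise ValueError("one label per voxel row required")
    present = set(labels)
    if node_ids is None:
        node_ids = sorted(present)
    else:
        node_ids = [str(n) for n in node_ids]
        unknown = present - set(node_ids)
        if unknown:
            raise ValueError(f"labels refer to undeclared nodes: {sorted(unknown)}")
        empty = [n for n in node_ids if n not in present]
        if empty:
            raise ValueError(f"node(s) with zero voxels: {empty}")
        node_ids = sorted(node_ids)
    rows = np.empty((len(node_ids), voxel_matrix.shape[1]))
    lab_arr = np.asarray(labels)
    for i, n in enumerate(node_ids):
        rows[i] = voxel_matrix[lab_arr == n].mean(axis=0)
    return TimeSeriesPanel(
        subject_id=subject_id, data=rows, node_ids=node_ids, condition=condition
    )
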