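"""Node -> functional-system partitions and system-type labels.

A partition assigns every cortical node to exactly one functional system
(e.g. default, frontoparietal, visual) and every system to a processing
type: ``sensory-motor`` systems handle sensory input and motor output,
``association`` systems support higher-order integrative cognition, and
``unassigned`` marks systems excluded from all segregation pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

SENSORY_MOTOR = "sensory-motor"
ASSOCIATION = "association"
UNASSIGNED = "unassigned"

_VALID_TYPES = {SENSORY_MOTOR, ASSOCIATION, UNASSIGNED}


@dataclass(frozen=True)
class SystemPartition:
    """Immutable node->system->type assignment.

    Parameters
    ----------
    node_ids :
        Ordered node identifiers; the order defines row/column order of
        every connectivity matrix built against this partition.
    system_of_node :
        System label for each node, aligned with ``node_ids``.
    type_of_system :
        Mapping from system label to one of ``sensory-motor``,
        ``association`` or ``unassigned``.
    """

    node_ids: tuple[str, ...]
    system_of_node: tuple[str, ...]
    type_of_system: dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        if len(self.node_ids) != len(self.system_of_node):
            raise FormatError("node_ids and system_of_node differ in length")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise FormatError("duplicate node_ids in partition")
        systems = set(self.system_of_node)
        missing = systems - set(self.type_of_system)
        if missing:
            raise FormatError(f"systems without a type label: {sorted(missing)}")
        bad = {t for t in self.type_of_system.values() if t not in _VALID_TYPES}
        if bad:
            raise FormatError(f"unknown system types: {sorted(bad)}")
        # Segregation needs at least two assigned systems with >= 2 nodes.
        sizes = self.system_sizes()
        big_assigned = [
            s for s, n in sizes.items()
            if n >= 2 and self.type_of_system[s] != UNASSIGNED
        ]
        if len(big_assigned) < 2:
            raise FormatError(
                "partition needs >= 2 assigned systems with >= 2 nodes each"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def systems(self, *, assigned_only: bool = False) -> list[str]:
        """Unique system labels in first-appearance order."""
        seen: list[str] = []
        for s in self.system_of_node:
            if s not in seen:
                if assigned_only and self.type_of_system[s] == UNASSIGNED:
                    continue
                seen.append(s)
        return seen

    def system_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for s in self.system_of_node:
            sizes[s] = sizes.get(s, 0) + 1
        return sizes

    def labels_array(self) -> np.ndarray:
        return np.asarray(self.system_of_node, dtype=object)

    def assigned_mask(self) -> np.ndarray:
        """Boolean mask over nodes whose system has a real type."""
        return np.asarray(
            [self.type_of_system[s] != UNASSIGNED for s in self.system_of_node]
        )

    def systems_of_type(self, system_type: str) -> list[str]:
        if system_type not in _VALID_TYPES:
            raise FormatError(f"unknown system type {system_type!r}")
        return [s for s in self.systems() if self.type_of_system[s] == system_type]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": list(self.node_ids),
                "system": list(self.system_of_node),
                "system_type": [self.type_of_system[s] for s in self.system_of_node],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SystemPartition":
        required = {"node_id", "system", "system_type"}
        if not required.issubset(df.columns):
            raise FormatError(f"partition table needs columns {sorted(required)}")
        type_of: dict[str, str] = {}
        for sys_label, t in zip(df["system"], df["system_type"]):
            prev = type_of.setdefault(sys_label, t)
            if prev != t:
                raise FormatError(f"system {sys_label!r} has conflicting types")
        return cls(
            node_ids=tuple(str(n) for n in df["node_id"]),
            system_of_node=tuple(str(s) for s in df["system"]),
            type_of_system=type_of,
        )

    @classmethod
    def from_tsv(cls, path) -> "SystemPartition":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


# Desk-scale default: 120 nodes in 10 systems of unequal size, 6 association
# and 4 sensory-motor, echoing the composition of common cortical atlases.
DEFAULT_SYSTEMS: tuple[tuple[str, int, str], ...] = (
    ("default", 20, ASSOCIATION),
    ("frontoparietal", 15, ASSOCIATION),
    ("cingulo-opercular", 15, ASSOCIATION),
    ("dorsal-attention", 10, ASSOCIATION),
    ("ventral-attention", 8, ASSOCIATION),
    ("salience", 7, ASSOCIATION),
    ("visual", 15, SENSORY_MOTOR),
    ("somatomotor-hand", 12, SENSORY_MOTOR),
    ("somatomotor-mouth", 8, SENSORY_MOTOR),
    ("auditory", 10, SENSORY_MOTOR),
)


def default_partition(
    systems: tuple[tuple[str, int, str], ...] = DEFAULT_SYSTEMS,
) -> SystemPartition:
    """Build the default desk-scale partition (120 nodes, 10 systems).

    ``systems`` is a tuple of ``(label, n_nodes, system_type)`` triples and
    can be overridden to scale the node count up or down.
    """
    node_ids: list[str] = []
    system_of_node: list[str] = []
    type_of: dict[str, str] = {}
    for label, n, stype in systems:
        if n < 1:
            raise FormatError(f"system {label!r} has no nodes")
        type_of[label] = stype
        for k in range(n):
            node_ids.append(f"{label}_{k + 1:02d}")
            system_of_node.append(label)
    return SystemPartition(
        node_ids=tuple(node_ids),
        system_of_node=tuple(system_of_node),
        type_of_system=type_of,
    )
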