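"""Venn partitioning of regulated-feature sets across two comparisons.

Eight pairwise-disjoint cells: common up, unique-to-A up, unique-to-B up,
the three down analogues, and the two discordant cells (up in one
comparison, down in the other).  "Unique to A" excludes features regulated
in B in *either* direction, so the cells tile the union exactly and the
marginal identities |A_up| = common_up + unique_A_up + discordant(A up,
B down) hold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["VennPartition", "venn_partition", "overlap_summary"]

CELL_NAMES = (
    "common_up",
    "unique_A_up",
    "unique_B_up",
    "common_down",
    "unique_A_down",
    "unique_B_down",
    "discordant_A_up_B_down",
    "discordant_A_down_B_up",
)


@dataclass(frozen=True)
class VennPartition:
    labels: tuple[str, str]
    common_up: frozenset[str]
    unique_A_up: frozenset[str]
    unique_B_up: frozenset[str]
    common_down: frozenset[str]
    unique_A_down: frozenset[str]
    unique_B_down: frozenset[str]
    discordant_A_up_B_down: frozenset[str]
    discordant_A_down_B_up: frozenset[str]

    def cells(self) -> dict[str, frozenset[str]]:
        return {name: getattr(self, name) for name in CELL_NAMES}

    def mirrored(self) -> "VennPartition":
        """The same partition seen from B's side (labels swapped)."""
        return VennPartition(
            labels=(self.labels[1], self.labels[0]),
            common_up=self.common_up,
            unique_A_up=self.unique_B_up,
            unique_B_up=self.unique_A_up,
            common_down=self.common_down,
            unique_A_down=self.unique_B_down,
            unique_B_down=self.unique_A_down,
            discordant_A_up_B_down=self.discordant_A_down_B_up,
            discordant_A_down_B_up=self.discordant_A_up_B_down,
        )


def venn_partition(
    A_up: frozenset[str] | set[str],
    A_down: frozenset[str] | set[str],
    B_up: frozenset[str] | set[str],
    B_down: frozenset[str] | set[str],
    labels: tuple[str, str] = ("A", "B"),
) -> VennPartition:
    """Partition two comparisons' up/down sets into the eight Venn cells."""
    A_up, A_down = frozenset(A_up), frozenset(A_down)
    B_up, B_down = frozenset(B_up), frozenset(B_down)
    if A_up & A_down:
        raise ValueError(
            f"up/down overlap within {labels[0]!r}: {sorted(A_up & A_down)}"
        )
    if B_up & B_down:
        raise ValueError(
            f"up/down overlap within {labels[1]!r}: {sorted(B_up & B_down)}"
        )
    B_any = B_up | B_down
    A_any = A_up | A_down
    return VennPartition(
        labels=labels,
        common_up=A_up & B_up,
        unique_A_up=A_up - B_any,
        unique_B_up=B_up - A_any,
        common_down=A_down & B_down,
        unique_A_down=A_down - B_any,
        unique_B_down=B_down - A_any,
        discordant_A_up_B_down=A_up & B_down,
        discordant_A_down_B_up=A_down & B_up,
    )


def overlap_summary(partition: VennPartition) -> dict[str, int]:
    """Cell cardinalities plus the four marginal totals."""
    counts = {name: len(cell) for name, cell in partition.cells().items()}
    counts["A_up_total"] = (
        counts["common_up"] + counts["unique_A_up"] + counts["discordant_A_up_B_down"]
    )
    counts["A_down_total"] = (
        counts["common_down"]
        + counts["unique_A_down"]
        + counts["discordant_A_down_B_up"]
    )
    counts["B_up_total"] = (
        counts["common_up"] + counts["unique_B_up"] + counts["discordant_A_down_B_up"]
    )
    counts["B_down_total"] = (
        counts["common_down"]
        + counts["unique_B_down"]
        + counts["discordant_A_up_B_down"]
    )
    return counts
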