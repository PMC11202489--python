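"""Study design: eggshell-colour groups and their replicate samples.

The default design mirrors the four-hen-group layout used throughout the
package: dark blue (DB), light blue (LB), dark-brown/greenish (DP) and the
pink control (PK), with 3, 3, 4 and 3 replicate shell-gland samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GROUPS = ("DB", "LB", "DP", "PK")
DEFAULT_REPLICATES = (3, 3, 4, 3)

#: The four group contrasts analysed by default, as (treatment, control).
DEFAULT_COMPARISONS = (
    ("DB", "PK"),
    ("LB", "PK"),
    ("DP", "PK"),
    ("DB", "DP"),
)


@dataclass(frozen=True)
class StudyDesign:
    """Ordered group labels and the replicate samples belonging to each."""

    groups: tuple[str, ...]
    samples_by_group: dict[str, tuple[str, ...]] = field(compare=False)

    @property
    def samples(self) -> list[str]:
        return [s for g in self.groups for s in self.samples_by_group[g]]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_of(self, sample: str) -> str:
        for g, members in self.samples_by_group.items():
            if sample in members:
                return g
        raise KeyError(f"unknown sample: {sample!r}")

    def sample_groups(self) -> dict[str, str]:
        """Map sample name -> group label, in design order."""
        return {s: g for g in self.groups for s in self.samples_by_group[g]}


def make_design(replicates_per_group: tuple[int, ...] = DEFAULT_REPLICATES,
                groups: tuple[str, ...] = GROUPS) -> StudyDesign:
    """Build a :class:`StudyDesign` with deterministic sample names.

    Samples are named ``<group><index>`` with 1-based indices (DB1, DB2, ...).
    Every group needs at least two replicates so that within-group variance
    is estimable downstream.
    """
    if len(replicates_per_group) != len(groups):
        raise ValueError(
            f"need one replicate count per group: got {len(replicates_per_group)} "
            f"counts for {len(groups)} groups")
    for g, n in zip(groups, replicates_per_group):
        if n < 2:
            raise ValueError(f"group {g}: at least 2 replicates required, got {n}")
    samples = {
        g: tuple(f"{g}{i}" for i in range(1, n + 1))
        for g, n in zip(groups, replicates_per_group)
    }
    return StudyDesign(groups=tuple(groups), samples_by_group=samples)
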