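"""Sample-to-group assignments (species hypotheses or inferred candidate species)."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Partition:
    """Assignment of samples to groups.

    ``assignment`` maps sample_id -> group label.  Group identity is by
    membership: two partitions are equivalent when they induce the same
    set of member sets, regardless of labels.
    """

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError("empty partition")

    @property
    def samples(self) -> list[str]:
        return list(self.assignment)

    def group_of(self, sample: str) -> str:
        return self.assignment[sample]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.assignment.items():
            out.setdefault(g, []).append(s)
        return out

    @property
    def n_groups(self) -> int:
        return len(set(self.assignment.values()))

    def member_sets(self) -> set[frozenset[str]]:
        return {frozenset(m) for m in self.groups().values()}

    def equivalent(self, other: "Partition") -> bool:
        """Same grouping of the same samples, ignoring labels."""
        return self.member_sets() == other.member_sets()

    def refines(self, other: "Partition") -> bool:
        """True when every group of self is contained in a group of other."""
        if set(self.assignment) != set(other.assignment):
            return False
        for members in self.groups().values():
            targets = {other.assignment[s] for s in members}
            if len(targets) != 1:
                return False
        return True

    def restrict(self, samples: list[str]) -> "Partition":
        return Partition({s: self.assignment[s] for s in samples})

    @classmethod
    def from_groups(cls, groups: dict[str, list[str]]) -> "Partition":
        return cls({s: g for g, members in groups.items() for s in members})
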