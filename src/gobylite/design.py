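"""Sample-to-group assignment with an explicit list of group comparisons."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

MAX_GROUPS = 10


@dataclass
class GroupDesign:
    """Groups of samples (at most 10) plus the ordered pairs to compare.

    A sample belongs to exactly one group; every comparison must reference
    two distinct defined groups. An arbitrary number of comparisons is
    allowed, each producing its own statistics block downstream.
    """

    groups: dict[str, list[str]]
    comparisons: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.groups:
            raise ValueError("design must define at least one group")
        if len(self.groups) > MAX_GROUPS:
            raise ValueError(
                f"at most {MAX_GROUPS} groups are supported, got {len(self.groups)}"
            )
        seen: dict[str, str] = {}
        for group, samples in self.groups.items():
            for sample in samples:
                if sample in seen:
                    raise ValueError(
                        f"sample {sample!r} assigned to both {seen[sample]!r} and {group!r}"
                    )
                seen[sample] = group
        for g1, g2 in self.comparisons:
            for g in (g1, g2):
                if g not in self.groups:
                    raise ValueError(f"comparison references undefined group {g!r}")
            if g1 == g2:
                raise ValueError(f"comparison {g1!r} vs itself is not meaningful")

    @property
    def samples(self) -> list[str]:
        return [s for samples in self.groups.values() for s in samples]

    def group_of(self, sample: str) -> str:
        for group, samples in self.groups.items():
            if sample in samples:
                return group
        raise KeyError(sample)


def read_design(
    path: str | Path, comparisons: list[tuple[str, str]] | None = None
) -> GroupDesign:
    """Read a two-column TSV (sample<TAB>group); header line optional."""
    groups: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}, line {i}: expected sample<TAB>group")
            sample, group = fields[0], fields[1]
            if i == 1 and (sample.lower(), group.lower()) == ("sample", "group"):
                continue
            groups.setdefault(group, []).append(sample)
    return GroupDesign(groups, comparisons or [])
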