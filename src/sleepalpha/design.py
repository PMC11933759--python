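"""Longitudinal cohort participation design.

The study design is an overlapping three-wave cohort: each participant is
present in some subset of months {1, 2, 3}. Month counts, pairwise
overlaps and the triple overlap must be mutually consistent under
inclusion-exclusion with the number of unique participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

MONTHS = (1, 2, 3)


@dataclass(frozen=True)
class CohortDesign:
    """Participation pattern: participant id -> set of months attended."""

    months_present: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        for pid, months in self.months_present.items():
            if not months:
                raise ValueError(f"participant {pid} attends no month")
            if not months <= set(MONTHS):
                raise ValueError(f"participant {pid} has months outside {MONTHS}")

    @property
    def n_participants(self) -> int:
        return len(self.months_present)

    def participants(self, months: set[int] | frozenset[int]) -> list[str]:
        """Participants present in *all* of the given months, sorted."""
        months = frozenset(months)
        return sorted(
            pid for pid, m in self.months_present.items() if months <= m
        )

    def month_count(self, month: int) -> int:
        return len(self.participants({month}))

    def overlap(self, *months: int) -> int:
        return len(self.participants(set(months)))

    @property
    def complete_participants(self) -> list[str]:
        """Participants present in all three months."""
        return self.participants(set(MONTHS))

    def check_inclusion_exclusion(self) -> None:
        """Verify the union identity over the three-month counts.

        |A∪B∪C| = Σ|Ai| − Σ|Ai∩Aj| + |A∩B∩C| must equal the number of
        unique participants. Always true for a membership map, but kept
        as an explicit audit used when validating externally supplied
        count patterns.
        """
        singles = sum(self.month_count(m) for m in MONTHS)
        pairs = sum(self.overlap(a, b) for a, b in combinations(MONTHS, 2))
        triple = self.overlap(*MONTHS)
        union = singles - pairs + triple
        if union != self.n_participants:
            raise ValueError(
                f"inclusion-exclusion union {union} != "
                f"{self.n_participants} participants"
            )

    def counts(self) -> dict[str, int]:
        """All seven printed-style counts, for reporting and validation."""
        return {
            "month1": self.month_count(1),
            "month2": self.month_count(2),
            "month3": self.month_count(3),
            "months12": self.overlap(1, 2),
            "months13": self.overlap(1, 3),
            "months23": self.overlap(2, 3),
            "all_three": self.overlap(1, 2, 3),
            "union": self.n_participants,
        }


def default_design() -> CohortDesign:
    """The study's printed participation pattern.

    Per-month 27/25/40, pairwise overlaps 24/25/23, 22 in all three
    months, 42 unique participants. Inclusion-exclusion over those counts
    forces a unique partition into membership cells: 22 attend all three,
    2 attend months {1,2} only, 3 attend {1,3} only, 1 attends {2,3}
    only, 14 attend month 3 only, and no one attends month 1 or month 2
    alone.
    """
    cells: list[tuple[frozenset[int], int]] = [
        (frozenset({1, 2, 3}), 22),
        (frozenset({1, 2}), 2),
        (frozenset({1, 3}), 3),
        (frozenset({2, 3}), 1),
        (frozenset({3}), 14),
    ]
    months_present: dict[str, frozenset[int]] = {}
    i = 1
    for months, count in cells:
        for _ in range(count):
            months_present[f"P{i:02d}"] = months
            i += 1
    design = CohortDesign(months_present)
    design.check_inclusion_exclusion()
    return design
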