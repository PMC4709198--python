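"""Head/tail/segment decomposition of an amphipathic ligand by atom name."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["LigandSchema", "default_fatty_acid_schema"]


@dataclass
class LigandSchema:
    """Atom-name decomposition of a fatty-acid-like ligand.

    ``segments`` must partition the head and tail atoms; carbons in
    ``tail_atoms`` are ordered from the carboxyl end toward the terminal
    methyl.  ``head_oxygen`` designates which carboxyl oxygen anchors
    head-to-tail distance measurements.  ``ch_pairs`` names the hydrogens
    bonded to each tail carbon (used for deuterium order parameters).
    """

    head_atoms: frozenset[str]
    tail_atoms: tuple[str, ...]
    head_oxygen: str
    segments: dict[str, frozenset[str]] = field(default_factory=dict)
    analysis_tail: frozenset[str] = frozenset()
    ch_pairs: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        self.head_atoms = frozenset(self.head_atoms)
        self.tail_atoms = tuple(self.tail_atoms)
        self.analysis_tail = frozenset(self.analysis_tail)
        if self.head_oxygen not in self.head_atoms:
            raise ValueError(
                f"designated head oxygen {self.head_oxygen!r} not in head_atoms"
            )
        everything = self.head_atoms | set(self.tail_atoms)
        if self.segments:
            union: set[str] = set()
            for label, members in self.segments.items():
                members = frozenset(members)
                self.segments[label] = members
                overlap = union & members
                if overlap:
                    raise ValueError(f"segment {label!r} overlaps others: {sorted(overlap)}")
                union |= members
            if union != everything:
                raise ValueError(
                    "segments must partition head∪tail atoms; "
                    f"missing {sorted(everything - union)}, extra {sorted(union - everything)}"
                )
        extra = self.analysis_tail - set(self.tail_atoms)
        if extra:
            raise ValueError(f"analysis_tail atoms not in tail: {sorted(extra)}")

    @property
    def terminal_carbon(self) -> str:
        return self.tail_atoms[-1]

    def part_of(self, atom_name: str) -> str | None:
        """'head' or 'tail' membership of an atom name, else None."""
        if atom_name in self.head_atoms:
            return "head"
        if atom_name in self.tail_atoms:
            return "tail"
        return None


def default_fatty_acid_schema(tail_length: int = 22) -> LigandSchema:
    """Schema for a C``tail_length`` fatty acid with the five-part sectioning
    HEAD + TAIL-A (C2-6), TAIL-B (C7-11), TAIL-C (C12-16), TAIL-D (C17-last)
    and the C12-terminal analysis tail used for head/tail discrimination.
    """
    if tail_length < 13:
        raise ValueError("tail_length must be >= 13 for the five-part scheme")
    carbons = [f"C{i}" for i in range(2, tail_length + 1)]
    head = frozenset({"O1", "O2", "C1"})
    seg = {
        "HEAD": head,
        "TAIL-A": frozenset(f"C{i}" for i in range(2, 7)),
        "TAIL-B": frozenset(f"C{i}" for i in range(7, 12)),
        "TAIL-C": frozenset(f"C{i}" for i in range(12, 17)),
        "TAIL-D": frozenset(f"C{i}" for i in range(17, tail_length + 1)),
    }
    return LigandSchema(
        head_atoms=head,
        tail_atoms=tuple(carbons),
        head_oxygen="O1",
        segments=seg,
        analysis_tail=frozenset(f"C{i}" for i in range(12, tail_length + 1)),
        ch_pairs={f"C{i}": (f"H{i}A", f"H{i}B") for i in range(2, tail_length + 1)},
    )
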