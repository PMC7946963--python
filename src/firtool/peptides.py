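"""Peptide sequences with per-residue phosphorylation marks.

:class:`ModifiedPeptide` is the shared currency between the motif scanner
and the mass-spec arithmetic.  Two annotation dialects are understood, both
in common use for phosphopeptides:

* ``prefix_p`` — ``pS`` / ``pT`` / ``pY`` (e.g. ``SDDpSDIVTLEPPK``)
* ``lowercase`` — ``s`` / ``t`` / ``y`` (e.g. ``LNSSGSSEDsFVEIR``)

Positions are 1-based within the peptide; ``numbering_offset`` maps them
onto the parent-protein coordinate system (offset = protein coordinate of
residue 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
PHOSPHO_ACCEPTORS = set("STY")


class PeptideParseError(ValueError):
    """Raised when an annotated sequence string cannot be parsed."""


@dataclass(frozen=True)
class ModifiedPeptide:
    """An amino-acid sequence with phospho marks at 1-based positions."""

    residues: str
    phospho: frozenset[int] = field(default_factory=frozenset)
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise PeptideParseError(f"unknown residue letter(s): {sorted(bad)}")
        for pos in self.phospho:
            if not 1 <= pos <= len(self.residues):
                raise PeptideParseError(
                    f"phospho position {pos} outside 1..{len(self.residues)}"
                )
            if self.residues[pos - 1] not in PHOSPHO_ACCEPTORS:
                raise PeptideParseError(
                    f"phospho mark on {self.residues[pos - 1]}{pos}; only S/T/Y accept phosphate"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def is_phospho(self, pos: int) -> bool:
        """True if the residue at 1-based peptide position *pos* is phosphorylated."""
        return pos in self.phospho

    def protein_coordinate(self, pos: int) -> int:
        """Parent-protein coordinate of peptide position *pos*."""
        return pos + self.numbering_offset - 1

    def with_phospho(self, pos: int) -> "ModifiedPeptide":
        """A copy with an additional phospho mark at *pos*."""
        return ModifiedPeptide(self.residues, self.phospho | {pos}, self.numbering_offset)

    def render(self, dialect: str = "prefix_p") -> str:
        out = []
        for i, aa in enumerate(self.residues, start=1):
            if i in self.phospho:
                out.append("p" + aa if dialect == "prefix_p" else aa.lower())
            else:
                out.append(aa)
        return "".join(out)


def parse_modified_sequence(
    text: str, dialect: str = "auto", numbering_offset: int = 1
) -> ModifiedPeptide:
    """Parse an annotated peptide string into a :class:`ModifiedPeptide`.

    Parameters
    ----------
    text
        Sequence with optional phospho marks (``pS``/``pT``/``pY`` or
        lowercase ``s``/``t``/``y`` depending on dialect).
    dialect
        ``prefix_p``, ``lowercase``, or ``auto`` (accept either; a ``p``
        followed by S/T/Y is always a prefix mark).
    numbering_offset
        Protein coordinate of the first residue.

    Raises
    ------
    PeptideParseError
        On empty input, dangling ``p``, or unrecognized characters; the
        message names the offending 1-based character position.
    """
    if dialect not in ("prefix_p", "lowercase", "auto"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if not text:
        raise PeptideParseError("empty sequence")

    residues: list[str] = []
    phospho: set[int] = set()
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "p" and dialect in ("prefix_p", "auto"):
            if i + 1 >= len(text) or text[i + 1].upper() not in PHOSPHO_ACCEPTORS:
                raise PeptideParseError(
                    f"'p' at character {i + 1} not followed by S, T or Y"
                )
            residues.append(text[i + 1].upper())
            phospho.add(len(residues))
            i += 2
            continue
        if ch.islower():
            if dialect == "prefix_p" or ch.upper() not in PHOSPHO_ACCEPTORS:
                raise PeptideParseError(
                    f"unexpected character {ch!r} at position {i + 1}"
                )
            residues.append(ch.upper())
            phospho.add(len(residues))
            i += 1
            continue
        if ch.upper() in AMINO_ACIDS and ch.isupper():
            residues.append(ch)
            i += 1
            continue
        raise PeptideParseError(f"unexpected character {ch!r} at position {i + 1}")

    return ModifiedPeptide("".join(residues), frozenset(phospho), numbering_offset)
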