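"""FIR/LIR core-motif scanning and Mode I/II classification.

The FIP200 Claw domain docks short linear motifs with the consensus core
grammar psi-Theta-x-x-Gamma:

* **psi** — the anchor: acidic Asp/Glu, or phosphorylated Ser/Thr.  An
  unmodified Ser/Thr is a *conditional* anchor (it can be switched on by
  kinase-mediated phosphorylation).
* **Theta** — the large-hydrophobic-pocket residue: Ile/Leu/Val or aromatic
  Phe/Tyr/Trp.  Canonical LIR motifs are the aromatic-Theta subset.
* **x** — any residue.
* **Gamma** — the small-hydrophobic-groove residue: Leu/Ile/Val.

Binding modes follow the anchor chemistry: Mode I is phosphorylation
independent (acidic psi), Mode II is phosphorylation dependent (phospho-Ser/
Thr psi), and ``conditional_II`` flags an unmodified Ser/Thr anchor that
would become Mode II upon phosphorylation.  Effective binding additionally
relies on an acidic stretch (Asp/Glu or phospho-Ser/Thr) in the window just
N-terminal of the anchor, summarized per hit in an :class:`ExtensionProfile`.

Phospho-Tyr is parsed but never satisfies psi: only Ser/Thr phosphorylation
creates the anchor.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Iterable, Optional, TextIO

import pandas as pd
from Bio import SeqIO

from .peptides import ModifiedPeptide, parse_modified_sequence

PSI_ACIDIC = set("DE")
PSI_PHOSPHO_ACCEPTOR = set("ST")
THETA_FIR = set("ILVFYW")
THETA_LIR = set("FYW")
GAMMA = set("LIV")

DEFAULT_WINDOW = 4


@dataclass(frozen=True)
class ExtensionProfile:
    """Composition of the N-terminal window preceding the psi anchor."""

    window: int
    n_acidic: int
    n_phospho: int
    n_st_unmod: int

    @property
    def acidic_ok(self) -> bool:
        """At least one acidic or phospho-S/T residue precedes the core."""
        return self.n_acidic + self.n_phospho >= 1


@dataclass(frozen=True)
class FirCoreMatch:
    """One psi-Theta-x-x-Gamma hit with its classification."""

    psi_pos: int  # 1-based peptide position of psi
    core: str  # rendered 5-residue core, phospho marks included
    psi_class: str  # acidic | phospho | conditional
    theta_class: str  # aliphatic | aromatic
    gamma: str
    mode: str  # I | II | conditional_II
    extension: ExtensionProfile
    enhancer_site: bool  # S/T (modified or not) immediately precedes psi
    protein_psi_pos: int  # psi in parent-protein coordinates

    @property
    def low_confidence(self) -> bool:
        """Core present but no acidic extension — 'core-only' hit."""
        return not self.extension.acidic_ok


def _psi_class(seq: ModifiedPeptide, pos: int, allow_conditional: bool) -> Optional[str]:
    aa = seq.residues[pos - 1]
    if aa in PSI_ACIDIC:
        return "acidic"
    if aa in PSI_PHOSPHO_ACCEPTOR:
        if seq.is_phospho(pos):
            return "phospho"
        if allow_conditional:
            return "conditional"
    return None


def _extension(seq: ModifiedPeptide, psi_pos: int, window: int) -> ExtensionProfile:
    start = max(1, psi_pos - window)
    n_acidic = n_phospho = n_st = 0
    for pos in range(start, psi_pos):
        aa = seq.residues[pos - 1]
        if aa in PSI_ACIDIC:
            n_acidic += 1
        elif aa in PSI_PHOSPHO_ACCEPTOR:
            if seq.is_phospho(pos):
                n_phospho += 1
            else:
                n_st += 1
    return ExtensionProfile(window, n_acidic, n_phospho, n_st)


def _match_at(
    seq: ModifiedPeptide,
    i: int,
    theta_set: set[str],
    allow_conditional: bool,
    window: int,
) -> Optional[FirCoreMatch]:
    psi_class = _psi_class(seq, i, allow_conditional)
    if psi_class is None:
        return None
    theta = seq.residues[i]  # position i+1
    if theta not in theta_set:
        return None
    gamma = seq.residues[i + 3]  # position i+4
    if gamma not in GAMMA:
        return None
    mode = {"acidic": "I", "phospho": "II", "conditional": "conditional_II"}[psi_class]
    prev = seq.residues[i - 2] if i >= 2 else ""
    core = "".join(
        ("p" + seq.residues[p - 1]) if seq.is_phospho(p) else seq.residues[p - 1]
        for p in range(i, i + 5)
    )
    return FirCoreMatch(
        psi_pos=i,
        core=core,
        psi_class=psi_class,
        theta_class="aromatic" if theta in THETA_LIR else "aliphatic",
        gamma=gamma,
        mode=mode,
        extension=_extension(seq, i, window),
        enhancer_site=prev in PSI_PHOSPHO_ACCEPTOR,
        protein_psi_pos=seq.protein_coordinate(i),
    )


def scan_fir_cores(
    seq: ModifiedPeptide,
    allow_conditional: bool = False,
    window: int = DEFAULT_WINDOW,
) -> list[FirCoreMatch]:
    """All psi-Theta-x-x-Gamma FIR cores in *seq*, ascending psi position.

    Overlapping matches are all reported; there is no greedy suppression.
    With ``allow_conditional``, unmodified Ser/Thr anchors are reported as
    ``conditional_II`` hits.  Sequences shorter than 5 residues yield an
    empty list.
    """
    hits = []
    for i in range(1, len(seq) - 3):
        m = _match_at(seq, i, THETA_FIR, allow_conditional, window)
        if m is not None:
            hits.append(m)
    return hits


def scan_lir_cores(seq: ModifiedPeptide, window: int = DEFAULT_WINDOW) -> list[FirCoreMatch]:
    """Canonical LIR cores: the aromatic-Theta (F/Y/W) subset of the FIR grammar.

    Every LIR hit is by construction also a strict FIR hit.
    """
    hits = []
    for i in range(1, len(seq) - 3):
        m = _match_at(seq, i, THETA_LIR, allow_conditional=False, window=window)
        if m is not None:
            hits.append(m)
    return hits


def classify_mode(match: FirCoreMatch) -> dict:
    """Mode label plus a rationale record for one match.

    The mode follows the anchor chemistry alone; a missing acidic extension
    downgrades confidence ("core-only, low-confidence") without changing
    the mode, and an S/T immediately preceding psi is flagged as a
    potential phospho-enhancer site.
    """
    return {
        "mode": match.mode,
        "acidic_ok": match.extension.acidic_ok,
        "enhancer_site": match.enhancer_site,
        "confidence": "core-only, low-confidence" if match.low_confidence else "full",
    }


REPORT_COLUMNS = [
    "record_id",
    "protein_psi_pos",
    "core",
    "mode",
    "theta_class",
    "n_acidic",
    "n_phospho",
    "n_st_unmod",
    "acidic_ok",
    "enhancer_site",
    "low_confidence",
]


def read_phospho_table(handle: TextIO | str) -> dict[str, set[int]]:
    """Read a two-column TSV of (record id, 1-based protein position)."""
    close = False
    if isinstance(handle, str):
        handle = open(handle)
        close = True
    try:
        table: dict[str, set[int]] = {}
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rec, pos = line.split("\t")[:2]
            table.setdefault(rec, set()).add(int(pos))
        return table
    finally:
        if close:
            handle.close()


def scan_fasta(
    records: Iterable | TextIO | str,
    phospho_table: Optional[dict[str, set[int]]] = None,
    allow_conditional: bool = False,
    window: int = DEFAULT_WINDOW,
    lir_only: bool = False,
    warn_stream: TextIO = sys.stderr,
) -> pd.DataFrame:
    """Scan a multi-record FASTA for FIR (or LIR) cores.

    *records* may be a path, an open handle, or pre-parsed SeqRecords.
    *phospho_table* maps record id to 1-based protein positions of
    phospho-Ser/Thr/Tyr sites; positions that fall outside a record or on a
    non-S/T/Y residue are skipped with a warning on *warn_stream*.
    Returns one row per match (record order, then position) with the fixed
    column order :data:`REPORT_COLUMNS`.
    """
    phospho_table = phospho_table or {}
    if isinstance(records, str) or hasattr(records, "read"):
        records = SeqIO.parse(records, "fasta")

    rows = []
    for rec in records:
        residues = str(rec.seq).upper()
        marks = set()
        for pos in sorted(phospho_table.get(rec.id, ())):
            if not 1 <= pos <= len(residues) or residues[pos - 1] not in "STY":
                print(
                    f"warning: {rec.id}: phospho position {pos} invalid, skipped",
                    file=warn_stream,
                )
                continue
            marks.add(pos)
        try:
            pep = ModifiedPeptide(residues, frozenset(marks))
        except ValueError as exc:
            print(f"warning: {rec.id}: {exc}; record skipped", file=warn_stream)
            continue
        scan = scan_lir_cores(pep, window) if lir_only else scan_fir_cores(
            pep, allow_conditional, window
        )
        for m in scan:
            rows.append(
                {
                    "record_id": rec.id,
                    "protein_psi_pos": m.protein_psi_pos,
                    "core": m.core,
                    "mode": m.mode,
                    "theta_class": m.theta_class,
                    "n_acidic": m.extension.n_acidic,
                    "n_phospho": m.extension.n_phospho,
                    "n_st_unmod": m.extension.n_st_unmod,
                    "acidic_ok": m.extension.acidic_ok,
                    "enhancer_site": m.enhancer_site,
                    "low_confidence": m.low_confidence,
                }
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


__all__ = [
    "ExtensionProfile",
    "FirCoreMatch",
    "scan_fir_cores",
    "scan_lir_cores",
    "classify_mode",
    "scan_fasta",
    "read_phospho_table",
    "parse_modified_sequence",
    "REPORT_COLUMNS",
]
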