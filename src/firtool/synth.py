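"""Synthetic inputs with ground truth for every pipeline stage.

Each generator is fully deterministic under its seed and returns the truth
alongside the data (never embedded in it), so scanners, fitters, peak
matchers and interface geometry can all be scored without any external
download:

* random proteomes with FIR/LIR cores implanted at known positions/modes;
* FP titrations drawn from the one-site depletion model at the measured
  affinities of the study system (phospho-Optineurin LIR / FIP200 Claw
  12 uM vs 307 uM unphosphorylated; p-CCPG1 FIR2 / GABARAP 9 uM vs 27 uM),
  with the labeled peptide at 0.25 uM;
* peak lists sampled from a theoretical b/y ladder plus decoys;
* toy coordinate sets with analytically known SASA or constructed
  hydrogen-bond ladders and pocket contacts.

Background residue frequencies are uniform over the 20 amino acids; no
attempt is made to mimic disorder propensity.  Titration noise is
homoscedastic Gaussian on the signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bindfit import TitrationCurve, simulate_titration
from .massspec import FragmentIon, fragment_ladder
from .peptides import ModifiedPeptide

AMINO_ACIDS_20 = "ACDEFGHIKLMNPQRSTVWY"

PSI_BY_MODE = {"I": "DE", "II": "ST", "conditional_II": "ST"}
THETA_FIR = "ILVFYW"
GAMMA = "LIV"


@dataclass
class ImplantTruth:
    record_id: str
    psi_pos: int  # 1-based protein coordinate of psi
    mode: str
    core: str
    phospho_positions: tuple[int, ...] = ()


@dataclass
class MotifFasta:
    fasta: str
    phospho_tsv: str
    truth: list[ImplantTruth] = field(default_factory=list)


def gen_motif_fasta(
    n_records: int,
    length: int = 200,
    modes: tuple[str, ...] = ("I", "II", "conditional_II"),
    seed: int | None = None,
    background: str = AMINO_ACIDS_20,
) -> MotifFasta:
    """Random protein records, each with one FIR core implanted.

    The implant satisfies the core grammar with an acidic dipeptide
    immediately N-terminal (so the extension flag is on); mode II implants
    come with a matching phospho-annotation row.  Incidental background
    hits are possible and not suppressed -- the truth table records only
    the implants, and callers should compare against a full scan oracle
    when exact equality is needed.
    """
    if length < 10:
        raise ValueError("record length must be >= 10")
    rng = np.random.default_rng(seed)
    bg = np.array(list(background))

    fasta_lines: list[str] = []
    tsv_lines: list[str] = []
    truth: list[ImplantTruth] = []
    for r in range(n_records):
        rec_id = f"synth{r:04d}"
        seq = list(rng.choice(bg, size=length))
        mode = modes[r % len(modes)]
        # core occupies psi..psi+4 with 2 acidic residues before it
        psi = int(rng.integers(3, length - 4))
        core = [
            str(rng.choice(list(PSI_BY_MODE[mode]))),
            str(rng.choice(list(THETA_FIR))),
            str(rng.choice(bg)),
            str(rng.choice(bg)),
            str(rng.choice(list(GAMMA))),
        ]
        seq[psi - 3 : psi - 1] = [str(rng.choice(list("DE"))) for _ in range(2)]
        seq[psi - 1 : psi + 4] = core
        phospho: tuple[int, ...] = ()
        if mode == "II":
            phospho = (psi,)
            tsv_lines.append(f"{rec_id}\t{psi}")
        rendered = "".join(core)
        if mode == "II":
            rendered = "p" + rendered
        truth.append(ImplantTruth(rec_id, psi, mode, rendered, phospho))
        fasta_lines.append(f">{rec_id} implanted mode {mode} at {psi}")
        s = "".join(seq)
        fasta_lines.extend(s[i : i + 60] for i in range(0, len(s), 60))
    return MotifFasta("\n".join(fasta_lines) + "\n", "\n".join(tsv_lines) + "\n", truth)


# Measured one-site affinities (uM) of the study system used as simulation
# truths: Optineurin LIR vs FIP200 Claw with/without pS177, and CCPG1 FIR2
# vs GABARAP with/without pS104.  Labeled peptide fixed at 0.25 uM.
TITRATION_PRESETS = {
    "pOPTN_FIP200": 12.0,
    "OPTN_FIP200": 307.0,
    "pCCPG1_GABARAP": 9.0,
    "CCPG1_GABARAP": 27.0,
}

_LT_UM = 0.25
_A_FREE = 50.0
_A_BOUND = 250.0
_NOISE_FRACTION = 0.01  # of the signal dynamic range
_REPLICATES = 3


def preset_design(name: str) -> dict:
    """Concentration design and truth parameters for a named preset."""
    if name not in TITRATION_PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(TITRATION_PRESETS)}")
    # 12 two-fold-spaced protein points from 0.5 uM; the weak binder
    # (Kd ~ 307 uM) extends the same series one step further, to ~2000 uM.
    n_points = 13 if name == "OPTN_FIP200" else 12
    return {
        "Kd": TITRATION_PRESETS[name],
        "Lt": _LT_UM,
        "Pt": 0.5 * 2.0 ** np.arange(n_points),
        "A_free": _A_FREE,
        "A_bound": _A_BOUND,
        "noise_sd": _NOISE_FRACTION * (_A_BOUND - _A_FREE),
        "replicates": _REPLICATES,
    }


def gen_titration_preset(name: str, seed: int | None = None) -> tuple[TitrationCurve, dict]:
    """Simulate a named FP titration; returns (curve, truth parameters)."""
    truth = preset_design(name)
    curve = simulate_titration(
        Kd=truth["Kd"],
        Lt=truth["Lt"],
        Pt=truth["Pt"],
        A_free=truth["A_free"],
        A_bound=truth["A_bound"],
        noise_sd=truth["noise_sd"],
        replicates=truth["replicates"],
        seed=seed,
    )
    return curve, truth


@dataclass
class SpectrumTruth:
    planted: list[FragmentIon]
    n_decoys: int
    tol_ppm: float


def gen_spectrum(
    p: ModifiedPeptide,
    fraction: float = 1.0,
    n_decoys: int = 0,
    jitter_ppm: float = 2.0,
    tol_ppm: float = 10.0,
    charges: tuple[int, ...] = (1,),
    seed: int | None = None,
) -> tuple[list[tuple[float, float]], SpectrumTruth]:
    """Peak list sampled from the theoretical b/y ladder, plus decoys.

    Planted peaks are jittered by at most *jitter_ppm*; decoy m/z values
    are rejected until they sit more than 3x *tol_ppm* away from every
    theoretical ion, so a matcher at *tol_ppm* can never pick one up.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    ladder = fragment_ladder(p, charges)
    k = max(1, int(round(fraction * len(ladder))))
    idx = rng.choice(len(ladder), size=k, replace=False)
    planted = [ladder[i] for i in sorted(idx)]

    peaks = []
    for ion in planted:
        jitter = rng.uniform(-jitter_ppm, jitter_ppm) * ion.mz * 1e-6
        peaks.append((ion.mz + jitter, float(rng.uniform(20.0, 100.0))))

    all_mz = np.array([ion.mz for ion in ladder])
    lo, hi = all_mz.min() - 50.0, all_mz.max() + 50.0
    made = 0
    while made < n_decoys:
        m = float(rng.uniform(lo, hi))
        if np.min(np.abs(all_mz - m)) > 3.0 * tol_ppm * m * 1e-6:
            peaks.append((m, float(rng.uniform(1.0, 20.0))))
            made += 1
    peaks.sort()
    return peaks, SpectrumTruth(planted, n_decoys, tol_ppm)


def peaks_to_csv(peaks: list[tuple[float, float]]) -> str:
    lines = ["mz,intensity"]
    lines += [f"{m:.6f},{i:.3f}" for m, i in peaks]
    return "\n".join(lines) + "\n"


def _pdb_atom(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    x: float,
    y: float,
    z: float,
    element: str,
) -> str:
    nm = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {nm}{'':1s}{resname:>3s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def gen_toy_structure(kind: str, separation: float = 100.0, n_pairs: int = 4) -> tuple[str, dict]:
    """Small synthetic PDB fixtures with geometric ground truth.

    * ``sphere_pair`` -- two isolated carbon atoms *separation* apart on
      chains A/B; truth carries the closed-form isolated-sphere SASA.
    * ``beta_pair`` -- two idealized antiparallel glycine strands whose
      backbone N/O atoms are placed to form exactly ``2 * n_pairs``
      cross-strand hydrogen bonds at 2.9 A with ~127 degree donor angles.
    * ``claw_mock`` -- single-atom residues reusing the Claw pocket
      numbering (Y1564...F1582, chain A) plus a chain-B peptide whose
      I106 sits 4.0 A from LHP members and L109 4.0 A from SHG members.
    """
    lines: list[str] = []
    truth: dict = {"kind": kind}
    serial = 1

    def emit(name, resname, chain, resnum, x, y, z, element):
        nonlocal serial
        lines.append(_pdb_atom(serial, name, resname, chain, resnum, x, y, z, element))
        serial += 1

    if kind == "sphere_pair":
        emit("CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C")
        emit("CA", "ALA", "B", 1, separation, 0.0, 0.0, "C")
        r = 1.70 + 1.4
        truth["isolated_sasa"] = 4.0 * math.pi * r * r
        truth["separation"] = separation
    elif kind == "beta_pair":
        expected = []
        for i in range(n_pairs):
            x0 = 5.0 * i  # stride chosen so each N's covalent antecedent is its own CA
            # strand A residue i+1
            emit("N", "GLY", "A", i + 1, x0, 0.0, 0.0, "N")
            emit("CA", "GLY", "A", i + 1, x0 + 1.2, -0.9, 0.0, "C")
            emit("C", "GLY", "A", i + 1, x0 + 2.3, 0.0, 0.0, "C")
            emit("O", "GLY", "A", i + 1, x0 + 2.3, 1.23, 0.0, "O")
            # strand B partner, antiparallel, 2.9 A H-bond distances
            emit("N", "GLY", "B", n_pairs - i, x0 + 2.3, 4.13, 0.0, "N")
            emit("CA", "GLY", "B", n_pairs - i, x0 + 3.5, 5.03, 0.0, "C")
            emit("C", "GLY", "B", n_pairs - i, x0, 4.13, 0.0, "C")
            emit("O", "GLY", "B", n_pairs - i, x0, 2.9, 0.0, "O")
            expected.append((("A", i + 1, "N"), ("B", n_pairs - i, "O")))
            expected.append((("B", n_pairs - i, "N"), ("A", i + 1, "O")))
        truth["n_hbonds"] = 2 * n_pairs
        truth["pairs"] = expected
    elif kind == "claw_mock":
        lhp = {1565: "CYS", 1567: "ALA", 1574: "PHE", 1576: "VAL", 1582: "PHE"}
        shg = {1564: "TYR", 1581: "LYS"}
        for j, (num, rn) in enumerate(sorted(lhp.items())):
            emit("CA", rn, "A", num, 2.0 * j, 0.0, 0.0, "C")
        for j, (num, rn) in enumerate(sorted(shg.items())):
            emit("CA", rn, "A", num, 2.0 * j, 20.0, 0.0, "C")
        # peptide: I106 near the LHP cluster, L109 near the SHG cluster,
        # and a far-away spacer residue with no contacts
        emit("CA", "ILE", "B", 106, 4.0, 3.0, 0.0, "C")
        emit("CA", "LEU", "B", 109, -3.0, 21.0, 0.0, "C")
        emit("CA", "GLY", "B", 112, 50.0, 50.0, 50.0, "C")
        truth["contacts"] = {
            ("B", 106, ""): [("LHP", 1567), ("LHP", 1574), ("LHP", 1576)],
            ("B", 109, ""): [("SHG", 1564)],
        }
    else:
        raise ValueError(f"unknown toy structure kind {kind!r}")

    lines.append("END")
    return "\n".join(lines) + "\n", truth


__all__ = [
    "MotifFasta",
    "ImplantTruth",
    "SpectrumTruth",
    "TITRATION_PRESETS",
    "gen_motif_fasta",
    "gen_titration_preset",
    "preset_design",
    "gen_spectrum",
    "gen_toy_structure",
    "peaks_to_csv",
]
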