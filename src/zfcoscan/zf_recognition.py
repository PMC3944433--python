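"""C2H2 zinc-finger detection and recognition-code PWM assignment.

A Cys2-His2 (C2H2) zinc finger reads 3-4 bp of DNA through four residues of
its recognition helix (helix positions -1, 2, 3 and 6).  Given a protein
sequence, this module locates every C2H2 repeat, looks those four residues up
in an empirical recognition-code table, and emits one position weight matrix
(PWM) per finger.  Fingers can be concatenated into a composite preference
and any PWM can be collapsed to an IUPAC consensus string.

The canonical repeat is matched with the PROSITE-style pattern
``C-x(2,4)-C-x(12)-H-x(3,5)-H`` scanned left to right without overlap.  The
first histidine sits at helix position 7, which places the specificity
residues at fixed offsets 5, 8, 9 and 12 (1-based) of the twelve residues
between the second cysteine and the first histidine.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

DNA_ALPHABET = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: IUPAC degeneracy codes keyed by the sorted tuple of bases they cover.
IUPAC_BY_BASES = {
    ("A",): "A", ("C",): "C", ("G",): "G", ("T",): "T",
    ("A", "G"): "R", ("C", "T"): "Y", ("C", "G"): "S", ("A", "T"): "W",
    ("G", "T"): "K", ("A", "C"): "M",
    ("C", "G", "T"): "B", ("A", "G", "T"): "D", ("A", "C", "T"): "H",
    ("A", "C", "G"): "V",
    ("A", "C", "G", "T"): "N",
}
BASES_BY_IUPAC = {code: set(bases) for bases, code in IUPAC_BY_BASES.items()}

#: Contact positions of the recognition helix, N-terminal to C-terminal.
CONTACT_POSITIONS = (-1, 2, 3, 6)

# Offsets (0-based) of helix positions -1, 2, 3, 6 within the 12-residue
# stretch between the second Cys and the first His (first His = helix 7).
_HELIX_OFFSETS = {-1: 4, 2: 7, 3: 8, 6: 11}

C2H2_PATTERN = re.compile(r"C[A-Z]{2,4}C([A-Z]{12})H[A-Z]{3,5}H")


class InputError(ValueError):
    """Raised for malformed user input (sequences, tables, coordinates)."""


class LookupError_(KeyError):
    """Raised when a residue/position pair is absent from a recognition table."""


# ---------------------------------------------------------------------------
# Position weight matrix
# ---------------------------------------------------------------------------

@dataclass
class PositionWeightMatrix:
    """Column-stochastic base-probability matrix over A, C, G, T.

    Parameters
    ----------
    probs
        Array of shape ``(4, width)``; rows in A, C, G, T order; every
        column sums to 1.
    name
        Identifier used in MEME output and reports.
    source
        One of ``finger``, ``concatenated``, ``de_novo``, ``random``,
        ``control``.
    """

    probs: np.ndarray
    name: str = "pwm"
    source: str = "finger"

    _SOURCES = frozenset({"finger", "concatenated", "de_novo", "random", "control"})

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise InputError(f"PWM probs must be 4xW, got shape {self.probs.shape}")
        if self.probs.shape[1] < 1:
            raise InputError("PWM width must be >= 1")
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise InputError("PWM entries must lie in [0, 1]")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise InputError("every PWM column must sum to 1 within 1e-9")
        if self.source not in self._SOURCES:
            raise InputError(f"unknown PWM source {self.source!r}")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def reverse_complement(self) -> "PositionWeightMatrix":
        """PWM describing the same sites read on the opposite strand."""
        return PositionWeightMatrix(self.probs[::-1, ::-1].copy(),
                                    name=self.name + "_rc", source=self.source)

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (uniform background)."""
        p = np.clip(self.probs, 1e-12, 1.0)
        return 2.0 + (p * np.log2(p)).sum(axis=0)

    @classmethod
    def from_consensus(cls, consensus: str, certainty: float = 1.0,
                      name: str = "pwm", source: str = "de_novo") -> "PositionWeightMatrix":
        """Build a PWM from an IUPAC string, spreading ``certainty`` mass
        uniformly over the covered bases and the remainder over the rest."""
        cols = []
        for ch in consensus.upper():
            try:
                bases = BASES_BY_IUPAC[ch]
            except KeyError:
                raise InputError(f"invalid IUPAC character {ch!r}") from None
            col = np.full(4, (1.0 - certainty) / max(1, 4 - len(bases))
                          if len(bases) < 4 else 0.0)
            for b in bases:
                col[DNA_ALPHABET.index(b)] = certainty / len(bases)
            cols.append(col / col.sum())
        return cls(np.column_stack(cols), name=name, source=source)


def consensus(pwm: PositionWeightMatrix, degenerate_threshold: float = 0.6) -> str:
    """IUPAC consensus of a PWM.

    Per column: if the top base's probability exceeds ``degenerate_threshold``
    it is emitted alone; otherwise the minimal IUPAC code covering every base
    whose probability is within the threshold of the maximum (at least
    ``degenerate_threshold * p_max``) is emitted.  Ties resolve toward the
    alphabetically first base.
    """
    if not 0 < degenerate_threshold <= 1:
        raise InputError("degenerate_threshold must be in (0, 1]")
    out = []
    for col in pwm.probs.T:
        pmax = col.max()
        if pmax > degenerate_threshold:
            out.append(DNA_ALPHABET[int(np.argmax(col))])
        else:
            bases = tuple(sorted(DNA_ALPHABET[i] for i in range(4)
                                 if col[i] >= degenerate_threshold * pmax))
            out.append(IUPAC_BY_BASES[bases])
    return "".join(out)


# ---------------------------------------------------------------------------
# MEME minimal format and matrix dumps
# ---------------------------------------------------------------------------

def write_meme(pwms: Sequence[PositionWeightMatrix], path: str | Path,
               background: Sequence[float] | None = None,
               nsites: int = 20) -> None:
    """Write PWMs in MEME minimal motif format (version 4)."""
    bg = np.asarray(background if background is not None else [0.25] * 4, float)
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", "",
             "Background letter frequencies",
             " ".join(f"{b} {q:.5f}" for b, q in zip(DNA_ALPHABET, bg)), ""]
    for pwm in pwms:
        lines.append(f"MOTIF {pwm.name}")
        lines.append(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                     f"nsites= {nsites} E= 0")
        for col in pwm.probs.T:
            lines.append(" ".join(f"{v:.6f}" for v in col))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def read_meme(path: str | Path) -> list[PositionWeightMatrix]:
    """Read PWMs from MEME minimal motif format."""
    pwms: list[PositionWeightMatrix] = []
    name = None
    rows: list[list[float]] = []
    expect = 0
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("MOTIF"):
            name = line.split()[1]
        elif line.startswith("letter-probability matrix"):
            m = re.search(r"w=\s*(\d+)", line)
            expect = int(m.group(1)) if m else 0
            rows = []
        elif expect and name and line and line[0] in "0123456789.":
            rows.append([float(x) for x in line.split()])
            if len(rows) == expect:
                probs = np.array(rows).T
                probs /= probs.sum(axis=0, keepdims=True)
                pwms.append(PositionWeightMatrix(probs, name=name, source="de_novo"))
                name, expect = None, 0
    return pwms


def write_pwm_tsv(pwm: PositionWeightMatrix, path: str | Path) -> None:
    """Tab-separated matrix dump: one row per position, columns A C G T."""
    lines = ["pos\tA\tC\tG\tT"]
    for j, col in enumerate(pwm.probs.T, start=1):
        lines.append(f"{j}\t" + "\t".join(f"{v:.6f}" for v in col))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Zinc-finger domains
# ---------------------------------------------------------------------------

@dataclass
class ZincFingerDomain:
    """A single C2H2 repeat located within a protein.

    ``span`` is 1-based inclusive residue coordinates; ``specificity_residues``
    are the amino acids at helix positions -1, 2, 3, 6 in that order.
    """

    index: int
    span: tuple[int, int]
    specificity_residues: str
    raw_sequence: str

    def __post_init__(self) -> None:
        if len(self.specificity_residues) != 4:
            raise InputError("expected exactly 4 specificity residues")
        for aa in self.specificity_residues:
            if aa not in AMINO_ACIDS:
                raise InputError(f"invalid specificity residue {aa!r}")


def extract_zinc_fingers(protein: str) -> list[ZincFingerDomain]:
    """Locate all C2H2 zinc fingers in ``protein``.

    Non-overlapping matches of ``C-x(2,4)-C-x(12)-H-x(3,5)-H`` are collected
    left to right (N- to C-terminal) and indexed from 1.  The four
    specificity residues are read from the fixed helix offsets.

    Raises
    ------
    InputError
        If the sequence is empty or contains a character outside the
        20-letter amino-acid alphabet.
    """
    if not protein:
        raise InputError("empty protein sequence")
    seq = protein.upper()
    for i, aa in enumerate(seq):
        if aa not in AMINO_ACIDS:
            raise InputError(f"invalid residue {aa!r} at position {i + 1}")
    fingers = []
    for idx, m in enumerate(C2H2_PATTERN.finditer(seq), start=1):
        helix12 = m.group(1)
        residues = "".join(helix12[_HELIX_OFFSETS[p]] for p in CONTACT_POSITIONS)
        fingers.append(ZincFingerDomain(
            index=idx,
            span=(m.start() + 1, m.end()),
            specificity_residues=residues,
            raw_sequence=m.group(0),
        ))
    return fingers


# ---------------------------------------------------------------------------
# Recognition table
# ---------------------------------------------------------------------------

@dataclass
class RecognitionTable:
    """Lookup from (helix contact position, residue) to base preferences.

    ``entries`` maps ``(position, amino_acid)`` to a length-4 probability
    vector over A, C, G, T.  Missing residues fall back to the uniform
    distribution when ``allow_fallback`` is set at lookup time.
    """

    entries: dict[tuple[int, str], np.ndarray]
    provenance: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for key, w in self.entries.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (4,) or np.any(w < 0):
                raise InputError(f"bad weights for {key}: {w}")
            total = w.sum()
            if total <= 0:
                raise InputError(f"zero-mass weights for {key}")
            clean[key] = w / total
        self.entries = clean

    def lookup(self, position: int, residue: str,
               allow_fallback: bool = True) -> np.ndarray:
        key = (position, residue.upper())
        if key in self.entries:
            return self.entries[key]
        if allow_fallback:
            logger.warning("no recognition entry for residue %s at helix "
                           "position %d; using uniform preference", residue, position)
            return np.full(4, 0.25)
        raise LookupError_(f"no recognition entry for residue {residue!r} "
                           f"at helix position {position}")

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str | None = None) -> "RecognitionTable":
        """Read a table in ``position  residue  pA  pC  pG  pT`` format."""
        entries: dict[tuple[int, str], np.ndarray] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise InputError(f"expected 6 tab-separated fields, got: {raw!r}")
            pos, aa = int(parts[0]), parts[1].upper()
            entries[(pos, aa)] = np.array([float(x) for x in parts[2:]])
        return cls(entries, provenance=provenance or str(path))

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"# {self.provenance}", "# position\tresidue\tpA\tpC\tpG\tpT"]
        for (pos, aa), w in sorted(self.entries.items()):
            lines.append(f"{pos}\t{aa}\t" + "\t".join(f"{v:.4f}" for v in w))
        Path(path).write_text("\n".join(lines) + "\n")


def load_default_recognition_table() -> RecognitionTable:
    """Load the recognition-code table shipped as package data."""
    ref = resources.files("zfcoscan").joinpath("data/recognition_table.tsv")
    with resources.as_file(ref) as path:
        return RecognitionTable.from_tsv(path, provenance="zfcoscan bundled table")


# ---------------------------------------------------------------------------
# Finger -> PWM
# ---------------------------------------------------------------------------

def finger_to_pwm(finger: ZincFingerDomain, table: RecognitionTable,
                  allow_fallback: bool = True) -> PositionWeightMatrix:
    """Predict a finger's 4-column base preference from the recognition code.

    Under the canonical antiparallel docking geometry, helix positions 6, 3
    and -1 contact the three bases of the core triplet read 5'->3' on the top
    strand, and helix position 2 contacts the fourth, cross-strand base; that
    column is stored complemented into top-strand coordinates.
    """
    col6 = table.lookup(6, finger.specificity_residues[3], allow_fallback)
    col3 = table.lookup(3, finger.specificity_residues[2], allow_fallback)
    colm1 = table.lookup(-1, finger.specificity_residues[0], allow_fallback)
    col2 = table.lookup(2, finger.specificity_residues[1], allow_fallback)
    probs = np.column_stack([col6, col3, colm1, col2[::-1]])  # row reversal = complement
    probs = probs / probs.sum(axis=0, keepdims=True)
    return PositionWeightMatrix(probs, name=f"finger_{finger.index}", source="finger")


def concatenate_finger_pwms(pwms: Sequence[PositionWeightMatrix],
                            overlap: int = 0) -> PositionWeightMatrix:
    """Join finger PWMs 5'->3' into one composite PWM.

    With ``overlap=1`` each junction column is the renormalized element-wise
    geometric mean of the flanking columns, reflecting the shared base of
    adjacent finger subsites.  Output width is ``sum(W_i) - overlap*(n-1)``.
    """
    if len(pwms) == 0:
        raise InputError("need at least one PWM to concatenate")
    if overlap not in (0, 1):
        raise InputError("overlap must be 0 or 1")
    if overlap >= min(p.width for p in pwms):
        raise InputError("overlap must be smaller than the narrowest PWM")
    if len(pwms) == 1:
        return pwms[0]
    cols = [pwms[0].probs]
    for nxt in pwms[1:]:
        if overlap == 1:
            left = cols[-1]
            merged = np.sqrt(left[:, -1] * nxt.probs[:, 0])
            if merged.sum() <= 0:
                merged = np.full(4, 0.25)
            merged = merged / merged.sum()
            cols[-1] = left[:, :-1]
            cols.append(merged[:, None])
            cols.append(nxt.probs[:, 1:])
        else:
            cols.append(nxt.probs)
    probs = np.concatenate([c for c in cols if c.shape[1] > 0], axis=1)
    return PositionWeightMatrix(probs, name="concatenated", source="concatenated")
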