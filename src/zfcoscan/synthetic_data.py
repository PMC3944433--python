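"""Seedable synthetic datasets emulating the structure of the real analysis.

The real inputs — a few hundred ChIP peak regions, a genome and a zinc-finger
protein — are emulated by: Markov-chain background windows; a planted 14-bp
motif (moderate information content, ~1.2 bits/column, consensus containing
the GTAG and RAAA finger preferences) placed near window centers in a
fraction of "peak" windows; a ground-truth table of planted offsets/strands;
and a six-finger C2H2 protein fixture whose recognition-code preferences
reproduce the expected finger consensi (finger 1 -> GTAG, finger 4 -> RAAA).

Everything is deterministic under a single integer seed so pipeline runs and
tests need no downloads.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .sequence_scan import (BackgroundModel, GenomicRegion, encode,
                            reverse_complement)
from .zf_recognition import (DNA_ALPHABET, InputError, PositionWeightMatrix,
                             RecognitionTable, load_default_recognition_table)

logger = logging.getLogger(__name__)

SPACER = 100          # N bases between windows in the synthetic genome
SPACER_CHAR = "N"

#: Mild genome-like dinucleotide bias (CpG and TpA depletion) applied to the
#: default order-2 background chain.
GENOME_LIKE_BIAS = np.array([
    # next:  A     C     G     T          previous
    [1.00, 1.00, 1.00, 1.00],   # A
    [1.00, 1.00, 0.50, 1.00],   # C  (CpG depleted)
    [1.00, 1.00, 1.00, 1.00],   # G
    [0.70, 1.00, 1.00, 1.00],   # T  (TpA depleted)
])

#: Consensus of the default planted motif; contains the finger-1 preference
#: GTAG and the finger-4 preference RAAA as subwords.
PLANTED_CONSENSUS = "GTAGCACGTGRAAA"
_STRONG = 0.86   # dominant-base probability, ~1.2 bits/column
_WEAK = (1 - _STRONG) / 3


def default_planted_pwm() -> PositionWeightMatrix:
    """Width-14 planted motif, ~1.2 bits/column on average.

    Every column puts 0.86 on the consensus base except the degenerate R
    column, which splits 0.45/0.45 between A and G.
    """
    cols = []
    for ch in PLANTED_CONSENSUS:
        if ch == "R":
            col = np.array([0.45, 0.05, 0.45, 0.05])
        else:
            col = np.full(4, _WEAK)
            col[DNA_ALPHABET.index(ch)] = _STRONG
        cols.append(col)
    return PositionWeightMatrix(np.column_stack(cols), name="planted_motif",
                                source="de_novo")


@dataclass
class SyntheticConfig:
    """Generation settings; the defaults define the study conditions."""

    n_positive_windows: int = 270
    n_background_windows: int = 270
    flank: int = 200
    background_order: int = 2
    composition: tuple[float, float, float, float] = (0.29, 0.21, 0.21, 0.29)
    plant_probability: float = 0.9
    placement_sd: float = 50.0
    strand_probability: float = 0.5
    seed: int = 1

    @property
    def window_length(self) -> int:
        return 2 * self.flank + 1

    def validate(self, planted_width: int) -> None:
        for name in ("plant_probability", "strand_probability"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InputError(f"{name} must lie in [0, 1]")
        if self.placement_sd <= 0:
            raise InputError("placement_sd must be positive")
        if self.window_length < planted_width:
            raise InputError("window shorter than the planted motif")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def make_background_model(config: SyntheticConfig) -> BackgroundModel:
    return BackgroundModel.from_composition(
        config.composition, order=config.background_order,
        dinuc_bias=GENOME_LIKE_BIAS if config.background_order > 0 else None)


def sample_background(n: int, length: int, order: int,
                      composition: Sequence[float], seed) -> list[str]:
    """Draw ``n`` background sequences from the (biased) Markov chain."""
    model = BackgroundModel.from_composition(
        np.asarray(composition, float), order=order,
        dinuc_bias=GENOME_LIKE_BIAS if order > 0 else None)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return model.sample(n, length, rng)


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def plant_motif(sequences: Sequence[str], pwm: PositionWeightMatrix,
                plant_probability: float, placement_sd: float,
                strand_probability: float, seed) -> tuple[list[str], pd.DataFrame]:
    """Plant at most one PWM draw per sequence (ZOOPS-compatible truth).

    The motif midpoint follows a truncated discrete Gaussian around the
    window center with standard deviation ``placement_sd`` bp; with
    probability ``strand_probability`` the instance is reverse-complemented
    before insertion.  Returns the modified sequences and a truth table with
    columns ``window_id, planted, offset, strand, instance``.
    """
    if placement_sd <= 0:
        raise InputError("placement_sd must be positive")
    W = pwm.width
    if any(len(s) < W for s in sequences):
        raise InputError("PWM wider than the shortest sequence")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    letters = np.array(list(DNA_ALPHABET))
    out = []
    truth = []
    for i, s in enumerate(sequences):
        L = len(s)
        rec = {"window_id": f"peak_{i + 1:04d}", "planted": False,
               "offset": -1, "strand": ".", "instance": ""}
        if rng.random() < plant_probability:
            center = L // 2
            offsets = np.arange(L - W + 1)
            mids = offsets + W // 2
            wts = np.exp(-0.5 * ((mids - center) / placement_sd) ** 2)
            wts /= wts.sum()
            o = int(rng.choice(offsets, p=wts))
            draw = "".join(letters[(rng.random(W)[:, None]
                                    > np.cumsum(pwm.probs.T, axis=1)).sum(axis=1)])
            strand = "-" if rng.random() < strand_probability else "+"
            inserted = reverse_complement(draw) if strand == "-" else draw
            s = s[:o] + inserted + s[o + W:]
            rec.update(planted=True, offset=o, strand=strand, instance=draw)
        out.append(s)
        truth.append(rec)
    return out, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus the paths it was written to."""

    config: SyntheticConfig
    positive_windows: list[str]
    background_windows: list[str]
    peaks: list[GenomicRegion]
    truth: pd.DataFrame
    genome: dict[str, str]
    planted_pwm: PositionWeightMatrix
    paths: dict[str, Path] = field(default_factory=dict)


def generate_dataset(config: SyntheticConfig,
                     planted_pwm: PositionWeightMatrix | None = None
                     ) -> SyntheticDataset:
    """Generate windows, truth and the synthetic genome in memory."""
    pwm = planted_pwm or default_planted_pwm()
    config.validate(pwm.width)
    rng = np.random.default_rng(config.seed)
    model = make_background_model(config)
    L = config.window_length
    raw = model.sample(config.n_positive_windows, L, rng)
    positives, truth = plant_motif(raw, pwm, config.plant_probability,
                                   config.placement_sd,
                                   config.strand_probability, rng)
    backgrounds = model.sample(config.n_background_windows, L, rng)
    truth["config_hash"] = config.config_hash()

    spacer = SPACER_CHAR * SPACER
    chrom = "chrS"
    parts = [spacer]
    peaks = []
    pos = SPACER
    for i, w in enumerate(positives):
        peaks.append(GenomicRegion(chrom, pos, pos + L, f"peak_{i + 1:04d}"))
        parts.append(w)
        parts.append(spacer)
        pos += L + SPACER
    for w in backgrounds:
        parts.append(w)
        parts.append(spacer)
    genome = {chrom: "".join(parts)}
    return SyntheticDataset(config, positives, backgrounds, peaks, truth,
                            genome, pwm)


def make_dataset(config: SyntheticConfig, outdir: str | Path,
                 planted_pwm: PositionWeightMatrix | None = None
                 ) -> SyntheticDataset:
    """Generate and write a complete dataset to ``outdir``.

    Emits genome FASTA, peaks BED, window FASTA files (positive and
    background), a truth TSV, a synthetic gene annotation BED and a YAML
    config manifest.  Re-extracting windows from the genome + BED reproduces
    the window FASTA exactly.
    """
    ds = generate_dataset(config, planted_pwm)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def write_fasta(path: Path, names: Sequence[str], seqs: Sequence[str]) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(names, seqs):
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")

    paths = {
        "genome": outdir / "genome.fasta",
        "peaks": outdir / "peaks.bed",
        "windows": outdir / "windows.fasta",
        "background_windows": outdir / "background_windows.fasta",
        "truth": outdir / "truth.tsv",
        "genes": outdir / "genes.bed",
        "protein": outdir / "protein.fasta",
        "recognition_table": outdir / "recognition_table.tsv",
        "manifest": outdir / "dataset.yaml",
    }
    write_fasta(paths["genome"], list(ds.genome), list(ds.genome.values()))
    with open(paths["peaks"], "w") as fh:
        for p in ds.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\n")
    write_fasta(paths["windows"], [p.id for p in ds.peaks], ds.positive_windows)
    write_fasta(paths["background_windows"],
                [f"bg_{i + 1:04d}" for i in range(len(ds.background_windows))],
                ds.background_windows)
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)

    # synthetic genes: one feature per positive window, shifted off-center so
    # nearest-gene assignment is exercised; every other pair shares a gene id
    with open(paths["genes"], "w") as fh:
        L = config.window_length
        for i, p in enumerate(ds.peaks):
            gid = f"CG{9000 + i // 2}"
            name = f"gene{i // 2 + 1}"
            start = p.start + L // 4
            fh.write(f"{p.chrom}\t{start}\t{start + L // 2}\t{gid}\t{name}\t+\n")

    protein, table = make_erm_like_protein_fixture()
    write_fasta(paths["protein"], ["erm_like_fixture"], [protein])
    table.to_tsv(paths["recognition_table"])

    cfg_dict = asdict(ds.config)
    cfg_dict["composition"] = list(cfg_dict["composition"])
    manifest = {"config": cfg_dict, "config_hash": config.config_hash(),
                "planted_consensus": PLANTED_CONSENSUS,
                "n_planted": int(ds.truth["planted"].sum())}
    paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=True))
    ds.paths = paths
    return ds


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning an ordered name -> sequence mapping."""
    seqs: dict[str, list[str]] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = []
        elif name is not None:
            seqs[name].append(line.strip())
    return {k: "".join(v) for k, v in seqs.items()}


# ---------------------------------------------------------------------------
# Protein fixture
# ---------------------------------------------------------------------------

# specificity residues (helix -1, 2, 3, 6) for the six fixture fingers; under
# the bundled table finger 1 reads GTAG and finger 4 reads RAAA
_FIXTURE_FINGERS = [
    ("N", "E", "K", "R"),   # finger 1 -> GTAG
    ("R", "N", "Q", "E"),   # finger 2
    ("K", "R", "H", "N"),   # finger 3
    ("Q", "K", "N", "G"),   # finger 4 -> RAAA
    ("E", "Q", "R", "K"),   # finger 5
    ("T", "H", "E", "Q"),   # finger 6
]

_LINKER = "TGEKP"   # classic C2H2 inter-finger linker


def _finger_repeat(residues: tuple[str, str, str, str]) -> str:
    """One C2H2 repeat: C-x2-C-x12-H-x3-H with the specificity residues at
    helix offsets 5, 8, 9, 12 of the 12-mer (first His = helix position 7)."""
    rm1, r2, r3, r6 = residues
    helix12 = "FSDA" + rm1 + "LK" + r2 + r3 + "IS" + r6
    assert len(helix12) == 12
    return "C" + "AE" + "C" + helix12 + "H" + "AGS" + "H"


def make_erm_like_protein_fixture() -> tuple[str, RecognitionTable]:
    """Six-finger C2H2 fixture protein plus the bundled recognition table.

    The protein is synthetic: it is built so that exactly six canonical C2H2
    repeats are found and, under the bundled table, finger 1's consensus is
    GTAG and finger 4's is RAAA (the R column splitting 0.5/0.5 over A/G).
    """
    protein = "M" + "GSGS" + _LINKER.join(
        _finger_repeat(f) for f in _FIXTURE_FINGERS) + "GS"
    return protein, load_default_recognition_table()
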