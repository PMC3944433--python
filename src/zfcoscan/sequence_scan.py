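"""Window extraction, PWM log-odds scanning and preference enrichment.

Peak coordinates (BED-style, 0-based half-open) are expanded to fixed-flank
windows around the peak center, and PWMs are scanned over both strands with
log-odds scores in bits against a Markov background model.  Short IUPAC
preferences (the per-finger binding preferences) can be tested for
enrichment across a window set, and motif occurrences can be summarized as a
distance-to-peak-center histogram.

Scoring conventions
-------------------
* score(offset) = sum_j log2(p_j(base) / q(base)) with the PWM regularized by
  a pseudocount of ``0.25 * q_base`` per cell;
* the minus strand applies the PWM to the reverse complement, reported in
  top-strand coordinates;
* ambiguous bases (N etc.) contribute the background-expected log-odds of
  the column, which is close to zero, rather than minus infinity;
* ties break toward the smaller offset, then the plus strand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .zf_recognition import (BASES_BY_IUPAC, DNA_ALPHABET, InputError,
                             PositionWeightMatrix)

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 200
DEFAULT_PSEUDOCOUNT = 0.25

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(DNA_ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def encode(seq: str) -> np.ndarray:
    """Encode DNA as int8 codes: A=0, C=1, G=2, T=3, anything else 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Regions and background
# ---------------------------------------------------------------------------

@dataclass
class GenomicRegion:
    """BED-style region: 0-based half-open ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(f"bad region coordinates {self.chrom}:{self.start}-{self.end}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def read_bed(path) -> list[GenomicRegion]:
    """Read BED3+ regions; ids come from column 4 or are synthesized."""
    regions = []
    with open(path) as fh:
        for i, raw in enumerate(fh):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            rid = parts[3] if len(parts) > 3 and parts[3] not in (".", "") \
                else f"peak_{i + 1:04d}"
            regions.append(GenomicRegion(parts[0], int(parts[1]), int(parts[2]), rid))
    ids = [r.id for r in regions]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate region ids in BED input")
    return regions


@dataclass
class BackgroundModel:
    """Order-k Markov model over A, C, G, T.

    ``probs`` has shape ``(4,) * (order + 1)``: the last axis is the emitted
    base conditional on the k preceding bases.  ``marginals`` are the
    stationary single-base frequencies, used as the log-odds reference.
    """

    order: int
    probs: np.ndarray
    trained_on: str = ""
    marginals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (4,) * (self.order + 1):
            raise InputError(f"probs shape {self.probs.shape} inconsistent "
                             f"with order {self.order}")
        sums = self.probs.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise InputError("each conditional distribution must sum to 1")
        if self.marginals is None:
            self.marginals = self._stationary()
        self.marginals = np.asarray(self.marginals, dtype=float)
        self.marginals = self.marginals / self.marginals.sum()

    def _stationary(self) -> np.ndarray:
        if self.order == 0:
            return self.probs.copy()
        k = self.order
        nctx = 4 ** k
        flat = self.probs.reshape(nctx, 4)
        # context (b1..bk) -b-> (b2..bk, b)
        trans = np.zeros((nctx, nctx))
        for ctx in range(nctx):
            tail = (ctx % (4 ** (k - 1))) * 4 if k > 1 else 0
            for b in range(4):
                trans[ctx, tail + b] += flat[ctx, b]
        pi = np.full(nctx, 1.0 / nctx)
        for _ in range(500):
            new = pi @ trans
            done = np.abs(new - pi).max() < 1e-13
            pi = new
            if done:
                break
        marg = np.zeros(4)
        for ctx, w in enumerate(pi):
            marg[ctx % 4] += w  # last base of the context
        return marg / marg.sum()

    @classmethod
    def uniform(cls, order: int = 0) -> "BackgroundModel":
        return cls(order, np.full((4,) * (order + 1), 0.25),
                   trained_on="uniform")

    @classmethod
    def from_composition(cls, composition: Sequence[float], order: int = 0,
                         dinuc_bias: np.ndarray | None = None) -> "BackgroundModel":
        """Build a chain from base composition, optionally with a 4x4
        previous-base x next-base bias multiplier (e.g. CpG depletion)."""
        comp = np.asarray(composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or comp.sum() <= 0:
            raise InputError("composition must be 4 non-negative weights")
        comp = comp / comp.sum()
        if order == 0:
            return cls(0, comp, trained_on="composition")
        cond = np.empty((4, 4))
        for prev in range(4):
            w = comp * (dinuc_bias[prev] if dinuc_bias is not None else 1.0)
            cond[prev] = w / w.sum()
        probs = np.broadcast_to(cond, (4,) * (order - 1) + (4, 4)).copy()
        return cls(order, probs, trained_on="composition")

    @classmethod
    def from_sequences(cls, sequences: Iterable[str], order: int = 0,
                       pseudocount: float = 1.0) -> "BackgroundModel":
        """Train by counting (k+1)-mers over unambiguous stretches."""
        counts = np.full((4,) * (order + 1), pseudocount, dtype=float)
        base_counts = np.full(4, pseudocount, dtype=float)
        for seq in sequences:
            codes = encode(seq)
            base_counts += np.bincount(codes[codes < 4], minlength=4)[:4]
            if order == 0:
                continue
            for i in range(len(codes) - order):
                ctx = codes[i:i + order + 1]
                if np.any(ctx >= 4):
                    continue
                counts[tuple(ctx)] += 1
        if order == 0:
            counts = base_counts
        probs = counts / counts.sum(axis=-1, keepdims=True)
        return cls(order, probs, trained_on="sequences",
                   marginals=base_counts / base_counts.sum())

    def sample(self, n: int, length: int, rng: np.random.Generator) -> list[str]:
        """Draw ``n`` sequences of ``length`` bases; vectorized across rows."""
        if n == 0:
            return []
        k = self.order
        cum_marg = np.cumsum(self.marginals)
        if k == 0:
            u = rng.random((n, length))
            out = (u[..., None] > cum_marg).sum(axis=-1).astype(np.int8)
        else:
            out = np.empty((n, length), dtype=np.int8)
            flat_cum = np.cumsum(self.probs.reshape(-1, 4), axis=1)
            ctx = np.zeros(n, dtype=np.int64)
            for t in range(length):
                # warm up from the stationary marginals until k bases exist
                p = np.broadcast_to(cum_marg, (n, 4)) if t < k else flat_cum[ctx]
                u = rng.random(n)
                b = (u[:, None] > p).sum(axis=1).astype(np.int8)
                out[:, t] = b
                ctx = (ctx * 4 + b) % (4 ** k)
        letters = np.array(list(DNA_ALPHABET))
        return ["".join(row) for row in letters[out]]


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def _fetch(genome, chrom: str, start: int, end: int) -> str:
    piece = genome[chrom][start:end]
    return str(piece.seq if hasattr(piece, "seq") else piece).upper()


def _chrom_len(genome, chrom: str) -> int:
    return len(genome[chrom])


def extract_windows(peaks: Sequence[GenomicRegion], genome,
                    flank: int = DEFAULT_FLANK
                    ) -> tuple[list[tuple[GenomicRegion, str]], list[str]]:
    """Cut one ``[center - flank, center + flank + 1)`` window per peak.

    ``genome`` may be any mapping from chromosome name to sequence (a plain
    dict of strings or a :class:`pyfaidx.Fasta`).  Windows running off a
    chromosome end are clipped; a window clipped to zero length is dropped
    with a warning.  Returns ``(windows, dropped_ids)``.
    """
    if flank < 0:
        raise InputError("flank must be >= 0")
    names = set()
    for p in peaks:
        try:
            genome[p.chrom]
        except KeyError:
            names.add(p.chrom)
    if names:
        raise InputError("chromosomes missing from genome: "
                         + ", ".join(sorted(names)))
    windows: list[tuple[GenomicRegion, str]] = []
    dropped: list[str] = []
    for p in peaks:
        c = p.center
        lo = max(0, c - flank)
        hi = min(_chrom_len(genome, p.chrom), c + flank + 1)
        if hi <= lo:
            logger.warning("window for peak %s clipped to zero length; dropped", p.id)
            dropped.append(p.id)
            continue
        windows.append((GenomicRegion(p.chrom, lo, hi, p.id),
                        _fetch(genome, p.chrom, lo, hi)))
    return windows, dropped


# ---------------------------------------------------------------------------
# Log-odds scanning
# ---------------------------------------------------------------------------

def logodds_matrices(pwm: PositionWeightMatrix, background: BackgroundModel,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-strand log-odds lookup tables, shape (5, W).

    Row 4 holds the background-expected column score used for ambiguous
    bases.  The reverse table scores the PWM applied to the reverse
    complement while indexing top-strand codes left to right.
    """
    q = background.marginals
    p = pwm.probs + pseudocount * q[:, None]
    p = p / p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore"):  # zero cells allowed at pseudocount 0
        lo = np.log2(p / q[:, None])
    fwd = np.vstack([lo, q @ lo])
    rev_core = lo[::-1, ::-1]
    rev = np.vstack([rev_core, q @ rev_core])
    return fwd, rev


def sliding_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Per-offset scores for (n, L) coded sequences under a (5, W) table."""
    W = lom.shape[1]
    n, L = codes.shape
    m = L - W + 1
    if m < 1:
        raise InputError("sequence shorter than PWM width")
    S = np.zeros((n, m))
    for j in range(W):
        S += lom[codes[:, j:j + m], j]
    return S


@dataclass
class MotifOccurrence:
    """One motif hit inside a window, in top-strand window coordinates."""

    region_id: str
    offset: int
    strand: str
    score: float
    matched_sequence: str
    distance_to_center: int


@dataclass
class ScoredWindow:
    """Best motif hit for one window."""

    region: GenomicRegion
    sequence: str
    best_score: float
    best_offset: int
    best_strand: str


def scan_pwm(sequence: str, pwm: PositionWeightMatrix,
             background: BackgroundModel, threshold: float | None = None,
             region_id: str = "window", pseudocount: float = DEFAULT_PSEUDOCOUNT
             ) -> tuple[list[MotifOccurrence], tuple[float, int, str]]:
    """Scan one sequence on both strands.

    Returns ``(occurrences, (best_score, best_offset, best_strand))``.  With
    ``threshold=None`` only the best hit is reported as an occurrence.
    """
    W = pwm.width
    if len(sequence) < W:
        raise InputError(f"sequence length {len(sequence)} < PWM width {W}")
    codes = encode(sequence)[None, :]
    fwd, rev = logodds_matrices(pwm, background, pseudocount)
    sf = sliding_scores(codes, fwd)[0]
    sr = sliding_scores(codes, rev)[0]
    center = len(sequence) // 2

    def occ(o: int, strand: str, score: float) -> MotifOccurrence:
        return MotifOccurrence(region_id, int(o), strand, float(score),
                               sequence[o:o + W].upper(),
                               int(o + W // 2 - center))

    # best hit: max score; ties to smaller offset, then '+'
    bo_f, bo_r = int(np.argmax(sf)), int(np.argmax(sr))
    if sf[bo_f] >= sr[bo_r]:
        best = (float(sf[bo_f]), bo_f, "+")
        if sr[bo_r] == sf[bo_f] and bo_r < bo_f:
            best = (float(sr[bo_r]), bo_r, "-")
    else:
        best = (float(sr[bo_r]), bo_r, "-")

    if threshold is None:
        return [occ(best[1], best[2], best[0])], best
    occurrences = []
    for o in range(len(sf)):
        if sf[o] >= threshold:
            occurrences.append(occ(o, "+", sf[o]))
        if sr[o] >= threshold:
            occurrences.append(occ(o, "-", sr[o]))
    occurrences.sort(key=lambda x: (x.offset, x.strand))
    return occurrences, best


def best_scores(sequences: Sequence[str], pwm: PositionWeightMatrix,
                background: BackgroundModel,
                pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Best both-strand log-odds hit per sequence (vectorized over equal
    lengths; mixed lengths are grouped)."""
    fwd, rev = logodds_matrices(pwm, background, pseudocount)
    out = np.empty(len(sequences))
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(sequences):
        by_len.setdefault(len(s), []).append(i)
    for L, idx in by_len.items():
        if L < pwm.width:
            raise InputError(f"sequence length {L} < PWM width {pwm.width}")
        codes = np.stack([encode(sequences[i]) for i in idx])
        sf = sliding_scores(codes, fwd)
        sr = sliding_scores(codes, rev)
        out[idx] = np.maximum(sf.max(axis=1), sr.max(axis=1))
    return out


# ---------------------------------------------------------------------------
# Preference enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentReport:
    preference: str
    observed: int
    expected: float
    fold: float
    pvalue: float
    method: str
    n_windows: int

    @property
    def enriched(self) -> bool:
        return self.fold > 1.0 and self.pvalue < 0.05


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        bases = BASES_BY_IUPAC.get(ch)
        if bases is None:
            raise InputError(f"invalid IUPAC character {ch!r}")
        parts.append("[" + "".join(sorted(bases)) + "]")
    return re.compile("".join(parts))


def kmer_preference_enrichment(windows: Sequence[str], preference,
                               background: BackgroundModel,
                               n_null: int = 0, seed: int | None = None
                               ) -> EnrichmentReport:
    """Test whether windows containing the preference are overrepresented.

    ``preference`` is an IUPAC string (exact matching, both strands) or a
    PWM (a window matches when some offset scores above the PWM's 90th
    percentile background score quantile).  With ``n_null=0`` the expected
    count and one-sided p-value come from a closed-form binomial under the
    background's order-0 marginals; with ``n_null >= 100`` they come from
    resampled background window sets.
    """
    if len(windows) == 0:
        raise InputError("no windows given")
    q = background.marginals
    rng = np.random.default_rng(seed)

    if isinstance(preference, PositionWeightMatrix):
        W = preference.width
        fwd, rev = logodds_matrices(preference, background)
        null_seqs = background.sample(200, 500, rng)
        codes = np.stack([encode(s) for s in null_seqs])
        pool = np.concatenate([sliding_scores(codes, fwd).ravel(),
                               sliding_scores(codes, rev).ravel()])
        t90 = float(np.quantile(pool, 0.9))

        def has_match(seq: str) -> bool:
            c = encode(seq)[None, :]
            return bool((sliding_scores(c, fwd) >= t90).any()
                        or (sliding_scores(c, rev) >= t90).any())

        p_offset = 0.1  # by construction of the quantile threshold
        label = f"PWM:{preference.name}"
    else:
        pattern = str(preference).upper()
        W = len(pattern)
        sets = [BASES_BY_IUPAC.get(ch) for ch in pattern]
        if any(s is None for s in sets):
            raise InputError(f"invalid IUPAC preference {pattern!r}")
        if all(len(s) == 4 for s in sets):
            raise InputError("preference matches everything; uninformative")
        fre = _iupac_regex(pattern)
        rre = _iupac_regex(reverse_complement(pattern))

        def has_match(seq: str) -> bool:
            s = seq.upper()
            return bool(fre.search(s) or rre.search(s))

        qidx = {b: q[i] for i, b in enumerate(DNA_ALPHABET)}
        p_offset = float(np.prod([sum(qidx[b] for b in s) for s in sets]))
        label = pattern

    observed = sum(has_match(w) for w in windows)
    n = len(windows)

    if n_null >= 100:
        lengths = [len(w) for w in windows]
        null_counts = []
        for _ in range(n_null):
            reps = background.sample(n, max(lengths), rng)
            null_counts.append(sum(has_match(r[:L]) for r, L in zip(reps, lengths)))
        null_counts = np.asarray(null_counts)
        expected = float(null_counts.mean())
        pvalue = float((1 + (null_counts >= observed).sum()) / (1 + n_null))
        method = f"shuffle-null (n={n_null})"
    else:
        # P(window has >= 1 match), assuming independent offsets on 2 strands
        pw = np.array([1.0 - (1.0 - p_offset) ** (2 * max(0, len(w) - W + 1))
                       for w in windows])
        expected = float(pw.sum())
        pvalue = float(stats.binom.sf(observed - 1, n, float(pw.mean())))
        method = "binomial"

    fold = observed / expected if expected > 0 else float("inf")
    if observed == 0:
        fold, pvalue = 0.0, 1.0
    return EnrichmentReport(label, int(observed), expected, float(fold),
                            pvalue, method, n)


# ---------------------------------------------------------------------------
# Distance histogram
# ---------------------------------------------------------------------------

def peak_motif_distance_distribution(occurrences: Sequence[MotifOccurrence],
                                     bin_width: int = 20,
                                     range_bp: int = DEFAULT_FLANK):
    """Histogram of signed motif-midpoint-to-peak-center distances.

    Bins are half-open ``[lo, hi)`` spanning ``[-range_bp, +range_bp]`` with
    the final bin closed.  Returns a DataFrame with columns
    ``bin_lo, bin_hi, count, fraction``.
    """
    import pandas as pd

    if bin_width <= 0:
        raise InputError("bin_width must be positive")
    edges = np.arange(-range_bp, range_bp + 1e-9, bin_width)
    if edges[-1] < range_bp:
        edges = np.append(edges, range_bp)
    dists = np.array([o.distance_to_center for o in occurrences], dtype=float)
    counts, _ = np.histogram(dists, bins=edges)
    total = counts.sum()
    return pd.DataFrame({
        "bin_lo": edges[:-1].astype(int),
        "bin_hi": edges[1:].astype(int),
        "count": counts,
        "fraction": counts / total if total else np.zeros_like(counts, float),
    })


def write_occurrences_bed(occurrences: Sequence[MotifOccurrence],
                          regions: Mapping[str, GenomicRegion], path) -> None:
    """BED6 output for motif occurrences (score = bits x 100, rounded)."""
    lines = []
    for o in occurrences:
        r = regions[o.region_id]
        start = r.start + o.offset
        lines.append("\t".join([r.chrom, str(start),
                                str(start + len(o.matched_sequence)),
                                o.region_id, str(int(round(o.score * 100))),
                                o.strand]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
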