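"""Window extraction, log-odds scanning, enrichment and distance histograms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zfcoscan.sequence_scan import (BackgroundModel, GenomicRegion,
                                    extract_windows, kmer_preference_enrichment,
                                    peak_motif_distance_distribution,
                                    reverse_complement, scan_pwm, best_scores,
                                    MotifOccurrence)
from zfcoscan.zf_recognition import InputError, PositionWeightMatrix

DNA = "ACGT"


# ---------------------------------------------------------------------------
# Brute-force scanning oracle
# ---------------------------------------------------------------------------

def _oracle_scores(seq, pwm, q, pseudocount=0.25):
    """Per-offset, per-strand scores by direct enumeration: pseudocount the
    PWM, then sum log2(p/q) column by column; ambiguous bases contribute the
    background-expected column log-odds."""
    W = pwm.width
    p = pwm.probs + pseudocount * q[:, None]
    p = p / p.sum(axis=0)
    lo = np.log2(p / q[:, None])
    seq = seq.upper()

    def col_score(base, j, minus=False):
        if base in DNA:
            return lo[DNA.index(base), j]
        # ambiguous top-strand base ~ q; on the minus strand the motif reads
        # its complement, so the expectation uses complemented marginals
        if minus:
            return float(sum(q[3 - b] * lo[b, j] for b in range(4)))
        return float(sum(q[b] * lo[b, j] for b in range(4)))

    fwd, rev = [], []
    for o in range(len(seq) - W + 1):
        fwd.append(sum(col_score(seq[o + j], j) for j in range(W)))
        rc = reverse_complement(seq[o:o + W])
        rev.append(sum(col_score(rc[j], j, minus=True) for j in range(W)))
    return np.array(fwd), np.array(rev)


def _oracle_best(fwd, rev):
    best = (-np.inf, -1, "")
    for o in range(len(fwd)):
        for strand, s in (("+", fwd[o]), ("-", rev[o])):
            if s > best[0]:
                best = (s, o, strand)
    return best


def _random_seq(rng, length, n_frac=0.0):
    bases = list(DNA) + (["N"] if n_frac else [])
    p = [(1 - n_frac) / 4] * 4 + ([n_frac] if n_frac else [])
    return "".join(rng.choice(bases, size=length, p=p))


def test_scanner_matches_enumeration_oracle():
    """Occurrence sets and best hits equal brute-force enumeration on 500
    random (sequence, PWM) instances, including ambiguous bases."""
    rng = np.random.default_rng(3)
    bg = BackgroundModel.from_composition(rng.dirichlet([10] * 4))
    q = bg.marginals
    for i in range(500):
        W = int(rng.integers(4, 13))
        L = int(rng.integers(W, 201))
        pwm = PositionWeightMatrix(rng.dirichlet([1] * 4, size=W).T)
        seq = _random_seq(rng, L, n_frac=0.1 if i % 5 == 0 else 0.0)
        fwd, rev = _oracle_scores(seq, pwm, q)
        # threshold strictly between distinct score values so 1-ulp score
        # differences cannot flip inclusion at the boundary
        pool = np.sort(np.concatenate([fwd, rev]))
        target = pool[min(len(pool) - 1, max(1, int(0.8 * len(pool))))]
        distinct = np.unique(pool)
        idx = int(np.searchsorted(distinct, target))
        thresh = float((distinct[idx - 1] + distinct[idx]) / 2) if idx > 0 \
            else float(distinct[0] - 1.0)
        occs, best = scan_pwm(seq, pwm, bg, threshold=thresh)
        want = sorted([(o, "+", round(fwd[o], 9)) for o in range(len(fwd))
                       if fwd[o] >= thresh]
                      + [(o, "-", round(rev[o], 9)) for o in range(len(rev))
                         if rev[o] >= thresh])
        got = sorted((x.offset, x.strand, round(x.score, 9)) for x in occs)
        assert got == want
        ob = _oracle_best(fwd, rev)
        assert best[1:] == ob[1:] or math.isclose(best[0], ob[0], abs_tol=1e-9)
        assert math.isclose(best[0], ob[0], abs_tol=1e-9)


def test_consensus_sequence_scores_maximum():
    """A sequence equal to a one-hot PWM's consensus scores sum(log2(1/q))
    at offset 0 on the plus strand (no pseudocount)."""
    bg = BackgroundModel.from_composition([0.3, 0.2, 0.2, 0.3])
    pwm = PositionWeightMatrix.from_consensus("GATTACA")
    occs, best = scan_pwm("GATTACA", pwm, bg, pseudocount=0.0)
    q = {b: bg.marginals[i] for i, b in enumerate(DNA)}
    expected = sum(math.log2(1 / q[b]) for b in "GATTACA")
    assert best == (pytest.approx(expected), 0, "+")
    # reverse complement scores the same on the minus strand
    _, best_rc = scan_pwm(reverse_complement("GATTACA"), pwm, bg,
                          pseudocount=0.0)
    assert best_rc[0] == pytest.approx(expected)
    assert best_rc[2] == "-"


def test_scan_rejects_short_sequence(uniform_bg):
    pwm = PositionWeightMatrix.from_consensus("ACGTAC")
    with pytest.raises(InputError):
        scan_pwm("ACG", pwm, uniform_bg)


@given(st.text(alphabet="ACGT", min_size=8, max_size=60),
       st.integers(0, 2 ** 31 - 1))
@settings(max_examples=50, deadline=None)
def test_strand_symmetry(seq, seed):
    """Best score on S equals best score on reverse_complement(S)."""
    rng = np.random.default_rng(seed)
    pwm = PositionWeightMatrix(rng.dirichlet([1] * 4, size=5).T)
    bg = BackgroundModel.from_composition(rng.dirichlet([5] * 4))
    _, b1 = scan_pwm(seq, pwm, bg)
    _, b2 = scan_pwm(reverse_complement(seq), pwm, bg)
    assert b1[0] == pytest.approx(b2[0], abs=1e-9)


def test_best_scores_batch_agrees_with_scan(uniform_bg):
    rng = np.random.default_rng(6)
    pwm = PositionWeightMatrix(rng.dirichlet([1] * 4, size=8).T)
    seqs = [_random_seq(rng, int(rng.integers(20, 60))) for _ in range(30)]
    batch = best_scores(seqs, pwm, uniform_bg)
    singles = [scan_pwm(s, pwm, uniform_bg)[1][0] for s in seqs]
    np.testing.assert_allclose(batch, singles, atol=1e-9)


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def _genome(rng, chroms):
    return {c: _random_seq(rng, n) for c, n in chroms.items()}


def test_window_default_flank_length():
    rng = np.random.default_rng(1)
    genome = _genome(rng, {"chr1": 2000})
    peaks = [GenomicRegion("chr1", 900, 1100, "p1")]
    wins, dropped = extract_windows(peaks, genome, flank=200)
    assert not dropped
    region, seq = wins[0]
    assert len(seq) == 401
    assert (region.start, region.end) == (800, 1201)


def test_window_clipping_at_chromosome_start():
    rng = np.random.default_rng(2)
    genome = _genome(rng, {"chr1": 1000})
    peaks = [GenomicRegion("chr1", 40, 60, "p1")]   # center 50
    wins, dropped = extract_windows(peaks, genome, flank=200)
    assert not dropped
    assert len(wins[0][1]) == 251


def test_windows_match_substring_oracle_and_conserve_count():
    rng = np.random.default_rng(3)
    genome = _genome(rng, {"chr1": 5000, "chr2": 3000})
    peaks = []
    for i in range(20):
        chrom = "chr1" if rng.random() < 0.5 else "chr2"
        start = int(rng.integers(0, len(genome[chrom]) - 10))
        peaks.append(GenomicRegion(chrom, start, start + 10, f"p{i}"))
    wins, dropped = extract_windows(peaks, genome, flank=50)
    assert len(wins) + len(dropped) == len(peaks)
    by_id = {r.id: s for r, s in wins}
    for p in peaks:
        c = p.center
        want = genome[p.chrom][max(0, c - 50):min(len(genome[p.chrom]), c + 51)]
        assert by_id[p.id] == want.upper()


def test_missing_chromosome_is_keyed_error():
    genome = {"chr1": "ACGT" * 100}
    peaks = [GenomicRegion("chrX", 10, 20, "p1")]
    with pytest.raises(InputError, match="chrX"):
        extract_windows(peaks, genome)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def test_planted_preference_enriches(uniform_bg):
    rng = np.random.default_rng(4)
    windows = []
    for _ in range(50):
        w = list(_random_seq(rng, 30))
        w[10:14] = "GTAG"
        windows.append("".join(w))
    rep = kmer_preference_enrichment(windows, "GTAG", uniform_bg)
    assert rep.fold > 1 and rep.pvalue < 0.05 and rep.enriched


def test_zero_matches_boundary(uniform_bg):
    windows = ["AAAAAAAAAA"] * 20
    rep = kmer_preference_enrichment(windows, "GGGG", uniform_bg)
    assert rep.observed == 0 and rep.fold == 0.0 and rep.pvalue == 1.0


def test_binomial_pvalue_matches_tail_oracle():
    rng = np.random.default_rng(9)
    comp = np.array([0.3, 0.2, 0.2, 0.3])
    bg = BackgroundModel.from_composition(comp)
    windows = bg.sample(200, 80, rng)
    rep = kmer_preference_enrichment(windows, "GTAGA", bg)
    # independent tail: P(X >= obs) for X ~ Binom(n, p_window)
    p0 = comp[2] * comp[3] * comp[0] * comp[2] * comp[0]
    pw = 1 - (1 - p0) ** (2 * (80 - 5 + 1))
    tail = sum(math.comb(200, k) * pw ** k * (1 - pw) ** (200 - k)
               for k in range(rep.observed, 201))
    assert rep.pvalue == pytest.approx(tail, rel=1e-9)
    assert rep.expected == pytest.approx(200 * pw, rel=1e-9)


def test_uninformative_preference_rejected(uniform_bg):
    with pytest.raises(InputError):
        kmer_preference_enrichment(["ACGTACGT"] * 5, "NNNN", uniform_bg)


def test_enrichment_monotone_in_planted_matches(uniform_bg):
    rng = np.random.default_rng(15)
    windows = [_random_seq(rng, 40) for _ in range(40)]
    rep0 = kmer_preference_enrichment(windows, "GTAGGC", uniform_bg)
    for i in range(5):
        w = list(windows[i])
        w[5:11] = "GTAGGC"
        windows[i] = "".join(w)
        rep1 = kmer_preference_enrichment(windows, "GTAGGC", uniform_bg)
        assert rep1.observed >= rep0.observed
        assert rep1.fold >= rep0.fold
        rep0 = rep1


def test_shuffle_null_path(uniform_bg):
    rng = np.random.default_rng(12)
    windows = []
    for _ in range(30):
        w = list(_random_seq(rng, 25))
        w[3:7] = "GTAG"
        windows.append("".join(w))
    rep = kmer_preference_enrichment(windows, "GTAG", uniform_bg,
                                     n_null=150, seed=5)
    assert rep.method.startswith("shuffle-null")
    assert rep.fold > 1 and rep.pvalue < 0.05


# ---------------------------------------------------------------------------
# Distance histogram
# ---------------------------------------------------------------------------

def _occ(dist):
    return MotifOccurrence("r", 0, "+", 1.0, "ACGT", dist)


def test_single_center_occurrence():
    hist = peak_motif_distance_distribution([_occ(0)], bin_width=20,
                                            range_bp=200)
    assert hist["count"].sum() == 1
    row = hist[(hist.bin_lo <= 0) & (hist.bin_hi > 0)]
    assert row["count"].item() == 1
    assert hist.bin_lo.iloc[0] == -200 and hist.bin_hi.iloc[-1] == 200


def test_histogram_matches_brute_force_tally():
    rng = np.random.default_rng(4)
    dists = rng.integers(-200, 201, size=1000)
    hist = peak_motif_distance_distribution([_occ(int(d)) for d in dists])
    edges = list(range(-200, 201, 20))
    for lo, hi, count in zip(hist.bin_lo, hist.bin_hi, hist["count"]):
        if hi == edges[-1]:
            want = int(((dists >= lo) & (dists <= hi)).sum())
        else:
            want = int(((dists >= lo) & (dists < hi)).sum())
        assert count == want
    assert hist["count"].sum() == 1000
    assert hist["fraction"].sum() == pytest.approx(1.0)


def test_empty_histogram_is_all_zero():
    hist = peak_motif_distance_distribution([])
    assert (hist["count"] == 0).all() and (hist["fraction"] == 0).all()
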