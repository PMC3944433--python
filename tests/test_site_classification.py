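"""FDR calibration, AUC computation, null comparisons and gene annotation."""

import collections
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zfcoscan.sequence_scan import BackgroundModel, GenomicRegion
from zfcoscan.site_classification import (annotate_sites_to_genes,
                                          calibrate_fdr,
                                          column_shuffled_control,
                                          compare_negative_control,
                                          compute_auc, dinucleotide_shuffle,
                                          empirical_pvalues, random_motif_null,
                                          score_regions, shuffled_null_windows)
from zfcoscan.zf_recognition import InputError, PositionWeightMatrix


# ---------------------------------------------------------------------------
# FDR calibration
# ---------------------------------------------------------------------------

def test_perfect_separation_calls_everything():
    """All null scores below all observed scores: everything is called.

    The direct empirical FDR is exactly 0 above the null support, so every
    window is called at any alpha.  Empirical-BH is bounded by its p-value
    floor 1/(1 + n_null), so it calls everything whenever alpha is above the
    floor, but cannot reject below it.
    """
    observed = np.array([10.0, 11.0, 12.0])
    null = np.linspace(0, 5, 100)
    for alpha in (0.5, 0.05, 1e-4, 1e-8):
        calib, calls = calibrate_fdr(observed, null, alpha,
                                     method="direct-eFDR")
        assert calls.all()
        assert calib.threshold == 10.0
    calib, calls = calibrate_fdr(observed, null, 0.05)
    assert calls.all() and calib.threshold == 10.0
    # below the empirical p-value floor BH abstains rather than overclaims
    _, calls = calibrate_fdr(observed, null, 1e-4)
    assert not calls.any()


def test_bh_small_case_hand_computed():
    """5 observed vs null 1..10 at alpha 0.25: p = (1+#null>=s)/11, BH keeps
    the two smallest p-values (scores 12 and 11) only."""
    observed = np.array([12.0, 11.0, 9.0, 5.0, 0.0])
    null = np.arange(1.0, 11.0)
    pvals = empirical_pvalues(observed, null)
    np.testing.assert_allclose(pvals, [1 / 11, 1 / 11, 3 / 11, 7 / 11, 1.0])
    calib, calls = calibrate_fdr(observed, null, alpha=0.25)
    assert calls.tolist() == [True, True, False, False, False]
    assert calib.threshold == 11.0


def test_bh_agrees_with_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(31)
    observed = rng.normal(size=200)
    null = rng.normal(size=2000)
    pvals = empirical_pvalues(observed, null)
    for alpha in (0.01, 0.05, 0.2):
        _, calls = calibrate_fdr(observed, null, alpha)
        want = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
        np.testing.assert_array_equal(calls, want)


def test_exchangeable_null_rarely_calls():
    """Observed scores drawn from the null distribution: calls at alpha 0.01
    stay below 2% of windows in every replicate."""
    for seed in range(8, 28):
        rng = np.random.default_rng(seed)
        observed = rng.normal(size=1000)
        null = rng.normal(size=1000)
        _, calls = calibrate_fdr(observed, null, alpha=0.01)
        assert calls.sum() <= 20


def test_call_count_monotone_in_alpha():
    rng = np.random.default_rng(40)
    observed = np.concatenate([rng.normal(3, 1, 50), rng.normal(0, 1, 200)])
    null = rng.normal(0, 1, 5000)
    previous = None
    for alpha in (0.2, 0.1, 0.05, 0.01, 0.001, 1e-4):
        for method in ("empirical-BH", "direct-eFDR"):
            _, calls = calibrate_fdr(observed, null, alpha, method)
            if previous is not None and method == "empirical-BH":
                assert calls.sum() <= previous
        previous = calibrate_fdr(observed, null, alpha)[1].sum()


def test_direct_efdr_calls_are_top_scores():
    rng = np.random.default_rng(41)
    observed = np.concatenate([rng.normal(5, 0.5, 30), rng.normal(0, 1, 100)])
    null = rng.normal(0, 1, 5000)
    calib, calls = calibrate_fdr(observed, null, alpha=0.01,
                                 method="direct-eFDR")
    assert calls.any()
    assert observed[calls].min() >= observed[~calls].max()
    assert calib.method == "direct-eFDR"


def test_empty_null_rejected():
    with pytest.raises(InputError):
        calibrate_fdr(np.array([1.0]), np.array([]), 0.05)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def test_auc_boundaries():
    assert compute_auc([10] * 5, [1] * 7) == 1.0
    assert compute_auc([1] * 7, [10] * 5) == 0.0
    assert compute_auc([3, 4, 5], [3, 4, 5]) == pytest.approx(0.5)


def test_auc_matches_mann_whitney_oracle():
    rng = np.random.default_rng(12)
    for _ in range(100):
        n1, n2 = rng.integers(5, 100, size=2)
        pos = rng.integers(0, 20, size=n1).astype(float)  # force ties
        neg = rng.integers(0, 20, size=n2).astype(float)
        u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert compute_auc(pos, neg) == pytest.approx(u / (n1 * n2), abs=1e-12)
        # antisymmetry with tie credit is exact
        assert compute_auc(pos, neg) + compute_auc(neg, pos) == pytest.approx(1.0)


def test_auc_empty_rejected():
    with pytest.raises(InputError):
        compute_auc([], [1.0])


# ---------------------------------------------------------------------------
# Random-motif null and negative control
# ---------------------------------------------------------------------------

def test_random_motif_null_determinism_and_bounds(small_dataset):
    ds, bg = small_dataset
    kw = dict(width=8, n_motifs=25, positives=ds.positive_windows[:30],
              negatives=ds.background_windows[:30], background=bg, seed=5)
    s1 = random_motif_null(**kw)
    s2 = random_motif_null(**kw)
    np.testing.assert_array_equal(s1["aucs"], s2["aucs"])
    assert 0.0 <= s1["aucs"].min() and s1["aucs"].max() <= 1.0
    with pytest.raises(InputError):
        random_motif_null(8, 0, ds.positive_windows, ds.background_windows, bg)


def test_negative_control_report(small_dataset, default_dataset):
    ds, bg = default_dataset
    planted = ds.planted_pwm
    null = random_motif_null(planted.width, 60, ds.positive_windows,
                             ds.background_windows, bg, seed=13)
    control = column_shuffled_control(planted, seed=13)
    report = compare_negative_control(planted, control, ds.positive_windows,
                                      ds.background_windows, null, bg)
    # the planted motif discriminates; its shuffled-column copy does not
    assert not report["motif_within_null"]
    assert report["control_within_null"]
    # report AUCs equal independent recomputation
    ps = score_regions(ds.positive_windows, planted, bg)
    ns = score_regions(ds.background_windows, planted, bg)
    assert report["auc"] == pytest.approx(compute_auc(ps, ns))
    same = compare_negative_control(planted, planted, ds.positive_windows,
                                    ds.background_windows, null, bg)
    assert same["auc"] - same["control_auc"] == 0.0


def test_score_regions_order_contract(small_dataset):
    ds, bg = small_dataset
    pwm = ds.planted_pwm
    scores = score_regions(ds.positive_windows, pwm, bg)
    perm = np.random.default_rng(6).permutation(len(scores))
    permuted = score_regions([ds.positive_windows[i] for i in perm], pwm, bg)
    np.testing.assert_allclose(permuted, scores[perm])


# ---------------------------------------------------------------------------
# Dinucleotide shuffle
# ---------------------------------------------------------------------------

def _dinuc_counts(s):
    return collections.Counter(s[i:i + 2] for i in range(len(s) - 1))


def test_dinucleotide_shuffle_preserves_counts():
    rng = np.random.default_rng(9)
    for _ in range(25):
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 200))))
        shuf = dinucleotide_shuffle(seq, rng)
        assert len(shuf) == len(seq)
        assert shuf[0] == seq[0] and shuf[-1] == seq[-1]
        assert _dinuc_counts(shuf) == _dinuc_counts(seq)


def test_dinucleotide_shuffle_randomizes():
    rng = np.random.default_rng(10)
    seq = "".join(rng.choice(list("ACGT"), size=300))
    shufs = {dinucleotide_shuffle(seq, rng) for _ in range(5)}
    assert len(shufs) > 1


def test_shuffled_null_windows_count():
    rng = np.random.default_rng(11)
    windows = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(7)]
    null = shuffled_null_windows(windows, 20, seed=3)
    assert len(null) == 20
    assert all(len(w) == 50 for w in null)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def _genes(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "gene_id", "gene_name"])


def test_site_inside_gene_distance_zero():
    genes = _genes([("chr1", 100, 500, "+", "CG1", "g1")])
    sites = [GenomicRegion("chr1", 200, 300, "s1")]
    out = annotate_sites_to_genes(sites, genes)
    assert out.rows.iloc[0].gene_id == "CG1"
    assert out.rows.iloc[0].distance == 0


def test_many_to_one_mapping():
    genes = _genes([("chr1", 100, 500, "+", "CG1", "g1")])
    sites = [GenomicRegion("chr1", 200, 300, "s1"),
             GenomicRegion("chr1", 350, 420, "s2")]
    out = annotate_sites_to_genes(sites, genes)
    assert len(out.rows) == 2
    assert out.unique_genes == ["CG1"]


def test_annotation_matches_all_pairs_oracle():
    rng = np.random.default_rng(14)
    genes = _genes([("chr1", int(s), int(s) + int(rng.integers(50, 400)), "+",
                     f"CG{i}", f"g{i}")
                    for i, s in enumerate(rng.integers(0, 20_000, size=20))])
    sites = []
    for i in range(50):
        s = int(rng.integers(0, 20_000))
        sites.append(GenomicRegion("chr1", s, s + 30, f"s{i}"))
    out = annotate_sites_to_genes(sites, genes, max_distance=10 ** 9)
    by_site = {r.site_id: (r.gene_id, r.distance)
               for r in out.rows.itertuples()}
    for site in sites:
        c = site.center
        cand = []
        for g in genes.itertuples():
            d = max(0, g.start - c, c - (g.end - 1))
            cand.append((d, g.start, g.gene_id))
        want = min(cand)
        assert by_site[site.id] == (want[2], want[0])


def test_chromosome_namespace_mismatch():
    genes = _genes([("chr2", 0, 10, "+", "CG1", "g1")])
    with pytest.raises(InputError):
        annotate_sites_to_genes([GenomicRegion("chr1", 5, 9, "s")], genes)


def test_max_distance_leaves_sites_unassigned():
    genes = _genes([("chr1", 10_000, 10_100, "+", "CG1", "g1")])
    sites = [GenomicRegion("chr1", 0, 10, "s1")]
    out = annotate_sites_to_genes(sites, genes, max_distance=100)
    assert len(out.rows) == 0 and out.n_unassigned == 1
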