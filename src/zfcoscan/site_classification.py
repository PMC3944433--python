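"""Co-occupancy calling: FDR calibration, AUC validation, gene annotation.

Peak windows are scored by their best log-odds hit to the de novo motif.  An
empirical null (background-model windows or dinucleotide-preserving shuffles
of the peak windows) yields per-window empirical p-values; calls are made by
Benjamini-Hochberg at a target FDR (default alpha = 1e-4), with a direct
plug-in empirical-FDR threshold available as an alternative.  The motif's
discrimination of peak versus background windows is summarized as an AUC and
benchmarked against random Dirichlet-sampled PWMs of the same width, with an
optional negative-control motif compared against the same null.

The AUC here answers: how well does the best motif score separate peak
windows from composition-matched background windows?  Random motifs sit at
0.5 by construction, which anchors the scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_scan import BackgroundModel, best_scores, GenomicRegion
from .zf_recognition import InputError, PositionWeightMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 1e-4


def score_regions(windows: Sequence[str], motif, background: BackgroundModel
                  ) -> np.ndarray:
    """Best both-strand log-odds score per window, in input order."""
    pwm = motif.pwm if hasattr(motif, "pwm") else motif
    return best_scores(windows, pwm, background)


# ---------------------------------------------------------------------------
# FDR calibration
# ---------------------------------------------------------------------------

@dataclass
class FDRCalibration:
    null_scores: np.ndarray
    alpha: float
    threshold: float
    method: str
    n_null: int


def empirical_pvalues(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """p_i = (1 + #{null >= s_i}) / (1 + n_null)."""
    null_sorted = np.sort(null)
    n_null = len(null)
    ge = n_null - np.searchsorted(null_sorted, observed, side="left")
    return (1.0 + ge) / (1.0 + n_null)


def benjamini_hochberg(pvalues: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean mask of rejections at FDR level alpha."""
    n = len(pvalues)
    order = np.argsort(pvalues, kind="stable")
    thresholds = alpha * (np.arange(1, n + 1) / n)
    passing = pvalues[order] <= thresholds
    mask = np.zeros(n, dtype=bool)
    if passing.any():
        k = int(np.max(np.nonzero(passing)[0]))
        mask[order[:k + 1]] = True
    return mask


def calibrate_fdr(observed_scores: np.ndarray, null_scores: np.ndarray,
                  alpha: float = DEFAULT_ALPHA, method: str = "empirical-BH"
                  ) -> tuple[FDRCalibration, np.ndarray]:
    """Calibrate a score threshold against an empirical null and make calls.

    ``empirical-BH`` (default): per-window empirical p-values followed by
    Benjamini-Hochberg at ``alpha`` (pi0 = 1, conservative).
    ``direct-eFDR``: plug-in empirical FDR
    ``eFDR(s) = n_obs * FPR(s) / #{obs >= s}``, calling everything at or
    above the smallest score whose running-minimum eFDR is <= alpha.

    Returns the calibration record and a boolean call mask over windows.
    """
    observed = np.asarray(observed_scores, dtype=float)
    null = np.asarray(null_scores, dtype=float)
    if null.size == 0:
        raise InputError("empty null score sample")
    if not 0 < alpha < 1:
        raise InputError("alpha must lie in (0, 1)")
    if null.size < 1.0 / alpha:
        logger.warning("null sample (%d) smaller than 1/alpha (%.0f); "
                       "p-value floor %.2e exceeds alpha granularity",
                       null.size, 1.0 / alpha, 1.0 / (1 + null.size))
    if method == "empirical-BH":
        pvals = empirical_pvalues(observed, null)
        calls = benjamini_hochberg(pvals, alpha)
    elif method == "direct-eFDR":
        order = np.argsort(observed)[::-1]
        s_desc = observed[order]
        null_sorted = np.sort(null)
        fpr = (null.size - np.searchsorted(null_sorted, s_desc, side="left")) / null.size
        n_ge = np.arange(1, observed.size + 1)
        raw = np.minimum(1.0, observed.size * fpr / n_ge)
        # q-value monotonization: the best achievable eFDR using a threshold
        # at or below each score (accumulate the minimum from the bottom up)
        efdr = np.minimum.accumulate(raw[::-1])[::-1]
        calls = np.zeros(observed.size, dtype=bool)
        ok = np.nonzero(efdr <= alpha)[0]
        if ok.size:
            calls[order[:int(ok[-1]) + 1]] = True
    else:
        raise InputError(f"unknown FDR method {method!r}")
    threshold = float(observed[calls].min()) if calls.any() else float("inf")
    calib = FDRCalibration(np.sort(null), float(alpha), threshold, method,
                           int(null.size))
    return calib, calls


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def compute_auc(positive_scores: Sequence[float],
                negative_scores: Sequence[float]) -> float:
    """AUC = P(pos > neg) + 0.5 P(pos = neg), via the rank-sum statistic."""
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InputError("both score sets must be non-empty")
    ranks = _midranks(np.concatenate([pos, neg]))
    r_pos = ranks[:pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def random_motif_null(width: int, n_motifs: int, positives: Sequence[str],
                      negatives: Sequence[str], background: BackgroundModel,
                      dirichlet_alpha: float = 1.0, seed: int | None = None
                      ) -> dict:
    """AUC sample for random PWMs drawn column-wise from Dirichlet(alpha).

    Returns ``{"aucs", "mean", "sd", "n"}``; use :func:`null_percentile` to
    place an observed AUC within the sample.
    """
    if n_motifs < 1:
        raise InputError("n_motifs must be >= 1")
    if width < 4:
        raise InputError("width must be >= 4")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_motifs)
    for i in range(n_motifs):
        probs = rng.dirichlet([dirichlet_alpha] * 4, size=width).T
        pwm = PositionWeightMatrix(probs, name=f"random_{i}", source="random")
        ps = best_scores(positives, pwm, background)
        ns = best_scores(negatives, pwm, background)
        aucs[i] = compute_auc(ps, ns)
    return {"aucs": aucs, "mean": float(aucs.mean()),
            "sd": float(aucs.std(ddof=1)), "n": int(n_motifs)}


def null_percentile(value: float, sample: np.ndarray) -> float:
    """Empirical percentile (0-100) of ``value`` within ``sample``."""
    sample = np.asarray(sample)
    return float(100.0 * (sample < value).mean()
                 + 50.0 * (sample == value).mean())


def compare_negative_control(motif, control_motif, positives: Sequence[str],
                             negatives: Sequence[str],
                             null_sample: dict, background: BackgroundModel
                             ) -> dict:
    """Contrast a motif and a negative-control motif against the random null.

    ``control_within_null`` is true when the control's AUC falls inside the
    central 95% interval of the random-motif AUC sample.
    """
    pwm = motif.pwm if hasattr(motif, "pwm") else motif
    cpwm = control_motif.pwm if hasattr(control_motif, "pwm") else control_motif
    auc = compute_auc(best_scores(positives, pwm, background),
                      best_scores(negatives, pwm, background))
    cauc = compute_auc(best_scores(positives, cpwm, background),
                       best_scores(negatives, cpwm, background))
    lo, hi = np.quantile(null_sample["aucs"], [0.025, 0.975])
    return {
        "auc": auc,
        "control_auc": cauc,
        "auc_percentile": null_percentile(auc, null_sample["aucs"]),
        "control_percentile": null_percentile(cauc, null_sample["aucs"]),
        "null_interval_95": [float(lo), float(hi)],
        "motif_within_null": bool(lo <= auc <= hi),
        "control_within_null": bool(lo <= cauc <= hi),
    }


def column_shuffled_control(pwm: PositionWeightMatrix, seed: int | None = None
                            ) -> PositionWeightMatrix:
    """Negative-control motif: the same columns in random order."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pwm.width)
    return PositionWeightMatrix(pwm.probs[:, perm],
                                name=pwm.name + "_shuffled", source="control")


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle (Altschul-Erickson)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Constructs a random Eulerian walk on the dinucleotide multigraph with
    the original first and last characters fixed, following Altschul and
    Erickson's last-edge-tree construction.
    """
    s = seq.upper()
    if len(s) <= 2:
        return s
    chars = sorted(set(s))
    if len(chars) == 1:
        return s
    adj: dict[str, list[str]] = {c: [] for c in chars}
    for a, b in zip(s, s[1:]):
        adj[a].append(b)
    last = s[-1]
    verts = [c for c in chars if c != last]
    for _ in range(10_000):
        last_edge = {v: adj[v][rng.integers(len(adj[v]))] for v in verts
                     if adj[v]}
        # every vertex with out-edges must reach `last` through last-edges
        ok = True
        for v in last_edge:
            seen = set()
            cur = v
            while cur != last and cur in last_edge and cur not in seen:
                seen.add(cur)
                cur = last_edge[cur]
            if cur != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - virtually impossible for DNA-sized inputs
        raise ArithmeticError("failed to sample a last-edge tree")
    shuffled: dict[str, list[str]] = {}
    for v in chars:
        edges = list(adj[v])
        if v in last_edge:
            edges.remove(last_edge[v])
        order = rng.permutation(len(edges))
        edges = [edges[i] for i in order]
        if v in last_edge:
            edges.append(last_edge[v])
        shuffled[v] = edges
    out = [s[0]]
    ptr = {c: 0 for c in chars}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffled_null_windows(windows: Sequence[str], n_total: int,
                          seed: int | None = None) -> list[str]:
    """Dinucleotide-preserving shuffles of the windows, cycling until
    ``n_total`` null windows exist."""
    rng = np.random.default_rng(seed)
    out = []
    i = 0
    while len(out) < n_total:
        out.append(dinucleotide_shuffle(windows[i % len(windows)], rng))
        i += 1
    return out


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotationTable:
    """Site-to-nearest-gene assignments (many sites may share one gene)."""

    rows: pd.DataFrame  # site_id, gene_id, gene_name, distance
    unique_genes: list[str]
    n_unassigned: int


def annotate_sites_to_genes(called_sites: Sequence[GenomicRegion],
                            genes: pd.DataFrame,
                            max_distance: int = 10_000) -> GeneAnnotationTable:
    """Assign each called site to its nearest gene feature.

    ``genes`` needs columns ``chrom, start, end, strand, gene_id, gene_name``.
    Distance is from the site center to the feature interval (0 when the
    center lies inside).  Ties break toward the smaller gene start, then the
    lexicographically smaller id.  Sites farther than ``max_distance`` from
    every gene are left unassigned and counted.
    """
    required = {"chrom", "start", "end", "gene_id", "gene_name"}
    if not required.issubset(genes.columns):
        raise InputError(f"gene table must have columns {sorted(required)}")
    site_chroms = {s.chrom for s in called_sites}
    gene_chroms = set(genes["chrom"])
    orphan = site_chroms - gene_chroms
    if called_sites and not site_chroms & gene_chroms:
        raise InputError("no shared chromosomes between sites and genes: "
                         + ", ".join(sorted(orphan)))
    rows = []
    unassigned = 0
    for site in called_sites:
        sub = genes[genes["chrom"] == site.chrom]
        if sub.empty:
            unassigned += 1
            continue
        c = site.center
        dist = np.maximum(0, np.maximum(sub["start"].to_numpy() - c,
                                        c - (sub["end"].to_numpy() - 1)))
        best = sorted(zip(dist, sub["start"], sub["gene_id"], sub["gene_name"]))[0]
        if best[0] > max_distance:
            unassigned += 1
            continue
        rows.append({"site_id": site.id, "gene_id": best[2],
                     "gene_name": best[3], "distance": int(best[0])})
    df = pd.DataFrame(rows, columns=["site_id", "gene_id", "gene_name", "distance"])
    seen: list[str] = []
    for g in df["gene_id"]:
        if g not in seen:
            seen.append(g)
    return GeneAnnotationTable(df, seen, unassigned)
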