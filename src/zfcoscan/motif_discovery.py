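"""De novo motif discovery by z-score seeding and ZOOPS expectation-maximization.

The model is the classic ZOOPS mixture: each window carries zero or one
motif occurrence; an occurrence sits at a uniformly chosen offset and strand
and is emitted column-wise from the motif PWM, while all remaining bases are
emitted by an order-0 background.  The free parameters are the PWM and the
occurrence prior lambda (the probability that a window contains an
occurrence).

Discovery proceeds in three stages:

1. ``seed_candidates`` — rank k-mers by the z-score of the number of windows
   containing them (both strands) against the background expectation;
2. ``refine_em`` — expand a seed to the target width and run EM to
   convergence, tracking the log-likelihood trace;
3. ``select_width`` — refit at each candidate width and keep the model with
   the smallest BIC, ``-2*LL + (3W + 1) * ln(n)``.

All randomness flows through a single integer seed; reruns are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequence_scan import BackgroundModel, encode, reverse_complement
from .zf_recognition import (DNA_ALPHABET, InputError, PositionWeightMatrix,
                             consensus)

logger = logging.getLogger(__name__)

LL_SLACK = 1e-8  # permissible backward step from floating-point noise


@dataclass
class SeedCandidate:
    kmer: str
    count: int
    expected: float
    zscore: float


@dataclass
class EMTrace:
    """Iteration record of the EM objective (natural log).

    ``log_likelihoods`` holds the penalized log-likelihood the algorithm
    ascends: the data log-likelihood plus the Dirichlet (pseudocount)
    regularization term on the PWM.  This sequence is non-decreasing by the
    EM guarantee; the raw data log-likelihood alone is not, because the
    M-step is a MAP update.  ``raw_log_likelihoods`` holds the unpenalized
    data log-likelihood per iteration (used for BIC).
    """

    log_likelihoods: list[float]
    converged: bool
    n_iterations: int
    stop_reason: str
    raw_log_likelihoods: list[float] = field(default_factory=list)


@dataclass
class MotifModel:
    """Converged ZOOPS motif: PWM plus occurrence prior lambda."""

    pwm: PositionWeightMatrix
    occurrence_prior: float
    final_log_likelihood: float  # natural log (nats)

    @property
    def width(self) -> int:
        return self.pwm.width

    def consensus(self, degenerate_threshold: float = 0.6) -> str:
        return consensus(self.pwm, degenerate_threshold)


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def seed_candidates(windows: Sequence[str], k_range: Sequence[int],
                    background: BackgroundModel, top_n: int
                    ) -> list[SeedCandidate]:
    """Rank k-mers by how many windows contain them versus expectation.

    A window "contains" a k-mer when the k-mer or its reverse complement
    appears in the window.  Expectation and standard deviation use the
    independent-offset approximation under the background's order-0
    marginals; candidates are ranked by z-score across all k in ``k_range``
    with lexicographic tie-breaking.
    """
    if len(windows) == 0:
        raise InputError("no windows given")
    if top_n <= 0:
        return []
    q = {b: background.marginals[i] for i, b in enumerate(DNA_ALPHABET)}
    n = len(windows)
    candidates: list[SeedCandidate] = []
    for k in k_range:
        if k < 4 or k > min(len(w) for w in windows):
            raise InputError(f"seed length {k} outside [4, min window length]")
        counts: dict[str, int] = {}
        for w in windows:
            s = w.upper()
            present = set()
            for i in range(len(s) - k + 1):
                km = s[i:i + k]
                if all(c in q for c in km):
                    present.add(km)
                    present.add(reverse_complement(km))
            for km in present:
                counts[km] = counts.get(km, 0) + 1
        lengths = [len(w) for w in windows]
        for km, c in counts.items():
            p0 = float(np.prod([q[b] for b in km]))
            pw = np.array([1.0 - (1.0 - p0) ** (2 * (L - k + 1)) for L in lengths])
            exp = float(pw.sum())
            var = float((pw * (1 - pw)).sum())
            sd = np.sqrt(var)
            z = (c - exp) / sd if sd > 0 else 0.0
            candidates.append(SeedCandidate(km, c, exp, float(z)))
    candidates.sort(key=lambda s: (-s.zscore, s.kmer))
    return candidates[:top_n]


# ---------------------------------------------------------------------------
# ZOOPS EM
# ---------------------------------------------------------------------------

def _seed_pwm(seed: str, width: int, seed_weight: float) -> np.ndarray:
    """Center a seed consensus within ``width`` columns; seeded columns put
    ``seed_weight`` on the seed base plus a uniform remainder."""
    probs = np.full((4, width), 0.25)
    start = (width - len(seed)) // 2
    for j, ch in enumerate(seed.upper()):
        col = np.full(4, (1.0 - seed_weight) / 4)
        col[DNA_ALPHABET.index(ch)] += seed_weight
        probs[:, start + j] = col
    return probs


def refine_em(windows: Sequence[str], seed, width: int,
              background: BackgroundModel | None = None,
              max_iter: int = 200, tol: float = 1e-6,
              prior_init: float = 0.5, seed_weight: float = 0.7,
              pseudocount: float = 1.0) -> tuple[MotifModel, EMTrace]:
    """Fit the ZOOPS mixture at a fixed width starting from a seed.

    ``seed`` may be a k-mer string, a :class:`SeedCandidate` or a PWM whose
    probabilities initialize the motif directly.  ``background`` defaults to
    order-0 marginals trained on the windows.  Convergence is declared when
    the relative log-likelihood change drops below ``tol``.
    """
    if len(windows) == 0:
        raise InputError("no windows given")
    if background is None:
        background = BackgroundModel.from_sequences(windows, order=0)
    q = np.asarray(background.marginals, dtype=float)

    if isinstance(seed, PositionWeightMatrix):
        if seed.width > width:
            raise InputError("seed PWM wider than target width")
        probs = _expand_pwm(seed.probs, width)
    else:
        kmer = seed.kmer if isinstance(seed, SeedCandidate) else str(seed)
        if len(kmer) > width:
            raise InputError(f"seed length {len(kmer)} exceeds width {width}")
        probs = _seed_pwm(kmer, width, seed_weight)

    if min(len(w) for w in windows) < width:
        raise InputError("width exceeds the shortest window")
    n = len(windows)
    W = width
    # group windows of equal length so the E-step stays matrix-shaped
    groups: dict[int, list[int]] = {}
    for i, w in enumerate(windows):
        groups.setdefault(len(w), []).append(i)
    gcodes = {L: np.stack([encode(windows[i]) for i in idx])
              for L, idx in groups.items()}

    # background log-likelihood of each full window (order-0; ambiguous bases
    # contribute their expected log-probability) -- constant across iterations
    logq = np.log(q)
    logq5 = np.append(logq, q @ logq)
    log_pbg_total = float(sum(logq5[c].sum() for c in gcodes.values()))

    lam = float(np.clip(prior_init, 1e-6, 1 - 1e-6))
    lls: list[float] = []       # raw data log-likelihood
    objectives: list[float] = []  # + Dirichlet pseudocount term (monotone)
    converged = False
    stop = "max_iter"
    for it in range(max_iter):
        # E-step: per-offset/strand likelihood ratios motif vs background
        p = np.clip(probs, 1e-9, 1.0)
        p = p / p.sum(axis=0, keepdims=True)
        lo = np.log(p) - logq[:, None]
        fwd = np.vstack([lo, q @ lo])
        rev_core = lo[::-1, ::-1]
        rev = np.vstack([rev_core, q @ rev_core])
        ll = log_pbg_total
        z_total = 0.0
        counts = np.zeros((5, W))
        counts_m = np.zeros((5, W))
        for L, codes in gcodes.items():
            m = L - W + 1
            ng = codes.shape[0]
            Sf = np.zeros((ng, m))
            Sr = np.zeros((ng, m))
            for j in range(W):
                Sf += fwd[codes[:, j:j + m], j]
                Sr += rev[codes[:, j:j + m], j]
            Af = np.exp(np.clip(Sf, -700, 700))
            Ar = np.exp(np.clip(Sr, -700, 700))
            total = Af.sum(axis=1) + Ar.sum(axis=1)
            denom = (1.0 - lam) + lam / (2 * m) * total
            ll += float(np.log(denom).sum())
            scale = lam / (2 * m) / denom
            Zf = Af * scale[:, None]
            Zr = Ar * scale[:, None]
            z_total += float(Zf.sum() + Zr.sum())
            for j in range(W):
                counts[:, j] += np.bincount(codes[:, j:j + m].ravel(),
                                            weights=Zf.ravel(), minlength=5)
                counts_m[:, j] += np.bincount(codes[:, j:j + m].ravel(),
                                              weights=Zr.ravel(), minlength=5)
        lls.append(ll)
        objectives.append(ll + pseudocount * float(q @ np.log(p).sum(axis=1)))
        if not np.isfinite(ll):
            raise ArithmeticError(f"non-finite log-likelihood at iteration {it}")
        if len(objectives) > 1:
            delta = objectives[-1] - objectives[-2]
            if abs(delta) / max(abs(objectives[-1]), 1.0) < tol:
                converged = True
                stop = "tol"
                break
        # M-step
        lam = float(np.clip(z_total / n, 1e-6, 1 - 1e-6))
        # minus-strand gather maps to complemented bases in reversed columns
        base = counts[:4] + counts_m[:4][::-1, ::-1]
        base += counts[4][None, :] * q[:, None]
        base += counts_m[4][::-1][None, :] * q[::-1][:, None]
        base += pseudocount * q[:, None]
        probs = base / base.sum(axis=0, keepdims=True)

    pwm = PositionWeightMatrix(probs, name=f"de_novo_w{W}", source="de_novo")
    model = MotifModel(pwm, occurrence_prior=lam, final_log_likelihood=lls[-1])
    trace = EMTrace(objectives, converged, len(objectives), stop,
                    raw_log_likelihoods=lls)
    _check_monotone(trace)
    return model, trace


def _expand_pwm(probs: np.ndarray, width: int) -> np.ndarray:
    out = np.full((4, width), 0.25)
    start = (width - probs.shape[1]) // 2
    out[:, start:start + probs.shape[1]] = probs
    return out


def _check_monotone(trace: EMTrace) -> None:
    ll = np.asarray(trace.log_likelihoods)
    drops = np.diff(ll) < -LL_SLACK
    if drops.any():
        raise ArithmeticError(
            f"EM log-likelihood decreased at iteration {int(np.argmax(drops)) + 1}")


# ---------------------------------------------------------------------------
# Width selection and orchestration
# ---------------------------------------------------------------------------

def bic(model: MotifModel, n_windows: int) -> float:
    """Bayesian information criterion with 3W + 1 free parameters."""
    p = 3 * model.width + 1
    return -2.0 * model.final_log_likelihood + p * np.log(n_windows)


def _best_subpwm(probs: np.ndarray, width: int) -> np.ndarray:
    """Contiguous ``width``-column sub-matrix with maximal information content."""
    p = np.clip(probs, 1e-12, 1.0)
    ic = 2.0 + (p * np.log2(p)).sum(axis=0)
    totals = np.convolve(ic, np.ones(width), mode="valid")
    start = int(np.argmax(totals))
    return probs[:, start:start + width].copy()


def select_width(windows: Sequence[str], seeds: Sequence,
                 widths: Sequence[int],
                 background: BackgroundModel | None = None,
                 criterion: str = "bic", **em_kwargs
                 ) -> tuple[MotifModel, EMTrace, list[dict]]:
    """Fit per candidate width, then pick the width minimizing the criterion;
    ties go to the smaller width.

    Only the widest candidate is fitted from the raw seeds; narrower widths
    are re-fitted from the highest-information sub-window of the wide fit.
    This keeps all widths phase-aligned on the same signal, so the criterion
    compares widths rather than accidental seed placements.
    """
    if len(widths) == 0:
        raise InputError("no candidate widths")
    if criterion != "bic":
        raise InputError(f"unknown selection criterion {criterion!r}")
    n = len(windows)
    table: list[dict] = []
    fits: dict[int, tuple[MotifModel, EMTrace]] = {}
    failures: dict[int, str] = {}
    wmax = max(widths)
    wide: MotifModel | None = None
    for seed in seeds:
        try:
            model, trace = refine_em(windows, seed, wmax,
                                     background=background, **em_kwargs)
        except (InputError, ArithmeticError) as exc:
            failures[wmax] = str(exc)
            continue
        if wide is None or model.final_log_likelihood > wide.final_log_likelihood:
            wide = model
            fits[wmax] = (model, trace)
    for w in sorted(widths):
        best = fits.get(w)
        inits: list = []
        if wide is not None and w < wmax:
            inits.append(PositionWeightMatrix(_best_subpwm(wide.pwm.probs, w),
                                              name=f"init_w{w}", source="de_novo"))
        elif wide is None:
            inits.extend(seeds)
        for init in inits:
            try:
                model, trace = refine_em(windows, init, w,
                                         background=background, **em_kwargs)
            except (InputError, ArithmeticError) as exc:
                failures[w] = str(exc)
                continue
            if best is None or model.final_log_likelihood > best[0].final_log_likelihood:
                best = (model, trace)
        if best is None:
            continue
        fits[w] = best
        table.append({"width": w, "log_likelihood": best[0].final_log_likelihood,
                      "bic": float(bic(best[0], n)),
                      "occurrence_prior": best[0].occurrence_prior,
                      "converged": best[1].converged})
    if not fits:
        raise InputError("every width failed: " + "; ".join(
            f"w={w}: {msg}" for w, msg in failures.items()))
    best_w = min(fits, key=lambda w: (bic(fits[w][0], n), w))
    model, trace = fits[best_w]
    return model, trace, table


@dataclass
class DiscoveryConfig:
    k_range: tuple[int, int] = (6, 8)       # inclusive seed lengths
    widths: tuple[int, ...] = (10, 12, 14, 16)
    top_n_seeds: int = 2
    max_iter: int = 200
    tol: float = 1e-6
    prior_init: float = 0.5
    seed_weight: float = 0.7
    pseudocount: float = 1.0
    seed: int = 1


def discover(windows: Sequence[str], config: DiscoveryConfig = DiscoveryConfig(),
             background: BackgroundModel | None = None
             ) -> tuple[MotifModel, dict]:
    """End-to-end discovery: seeding, per-width EM, width selection.

    Returns the best model and a manifest with the seed table, criterion
    table and EM trace summary.  Deterministic for a fixed config.
    """
    if background is None:
        background = BackgroundModel.from_sequences(windows, order=0)
    ks = range(config.k_range[0], config.k_range[1] + 1)
    seeds = seed_candidates(windows, list(ks), background, config.top_n_seeds)
    if not seeds:
        raise InputError("no seed candidates found")
    model, trace, table = select_width(
        windows, seeds, config.widths, background=background,
        max_iter=config.max_iter, tol=config.tol,
        prior_init=config.prior_init, seed_weight=config.seed_weight,
        pseudocount=config.pseudocount)
    manifest = {
        "seeds": [{"kmer": s.kmer, "count": s.count,
                   "expected": s.expected, "zscore": s.zscore} for s in seeds],
        "criterion": "bic",
        "criterion_table": table,
        "selected_width": model.width,
        "consensus": model.consensus(),
        "occurrence_prior": model.occurrence_prior,
        "final_log_likelihood": model.final_log_likelihood,
        "em": {"converged": trace.converged, "n_iterations": trace.n_iterations,
               "stop_reason": trace.stop_reason},
        "config": vars(config) | {"k_range": list(config.k_range),
                                  "widths": list(config.widths)},
    }
    logger.info("discovered width-%d motif %s (lambda=%.3f)",
                model.width, manifest["consensus"], model.occurrence_prior)
    return model, manifest
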