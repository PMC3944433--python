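"""Single-config orchestration of the full co-occupancy analysis.

Stages run in method order: zinc-finger PWM assignment, window extraction,
finger-preference enrichment, de novo motif discovery, FDR-calibrated site
calling with AUC validation, and nearest-gene annotation.  A run is fully
determined by one global integer seed; per-stage seeds derive from it via a
fixed counter scheme (``stage_seed = (seed * 1000 + counter) mod 2**31``)
recorded in the run manifest together with SHA-256 digests of every output.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .motif_discovery import DiscoveryConfig, discover
from .sequence_scan import (BackgroundModel, extract_windows,
                            kmer_preference_enrichment,
                            peak_motif_distance_distribution, read_bed,
                            scan_pwm)
from .site_classification import (annotate_sites_to_genes, calibrate_fdr,
                                  column_shuffled_control, compare_negative_control,
                                  compute_auc, random_motif_null, score_regions,
                                  shuffled_null_windows)
from .synthetic_data import (SyntheticConfig, make_background_model,
                             make_dataset, read_fasta)
from .zf_recognition import (InputError, RecognitionTable, consensus,
                             extract_zinc_fingers, finger_to_pwm,
                             load_default_recognition_table, read_meme,
                             write_meme)

logger = logging.getLogger(__name__)

_STAGE_COUNTERS = {
    "simulate": 0, "windows": 1, "enrich": 2, "discover": 3,
    "null": 4, "random_motifs": 5, "control": 6,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived per-stage seed: ``(seed * 1000 + counter) mod 2**31``."""
    return (global_seed * 1000 + _STAGE_COUNTERS[stage]) % (2 ** 31)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentSettings:
    n_null: int = 0            # 0 = closed-form binomial
    alpha: float = 0.05
    min_enriched_fingers: int = 0


@dataclass
class ClassificationSettings:
    alpha: float = 1e-4
    n_null: int = 50_000
    n_random_motifs: int = 200
    fdr_method: str = "empirical-BH"
    control_motif: str | None = None    # MEME file; default column-shuffle
    max_gene_distance: int = 10_000


@dataclass
class InputPaths:
    protein: str | None = None
    protein_id: str | None = None
    genome: str | None = None
    peaks: str | None = None
    genes: str | None = None
    recognition_table: str | None = None
    background_windows: str | None = None   # FASTA of negative windows


@dataclass
class PipelineConfig:
    synthetic: bool = True
    synthetic_config: SyntheticConfig = field(default_factory=SyntheticConfig)
    inputs: InputPaths = field(default_factory=InputPaths)
    flank: int = 200
    enrichment: EnrichmentSettings = field(default_factory=EnrichmentSettings)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    classification: ClassificationSettings = field(default_factory=ClassificationSettings)
    seed: int = 1
    outdir: str = "zfcoscan_out"


_SECTION_TYPES = {
    "synthetic_config": SyntheticConfig,
    "inputs": InputPaths,
    "enrichment": EnrichmentSettings,
    "discovery": DiscoveryConfig,
    "classification": ClassificationSettings,
}


def _build_section(cls, raw: dict, errors: list[str], prefix: str):
    known = cls.__dataclass_fields__
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            msg = f"unknown key '{prefix}{key}'"
            if hint:
                msg += f" (did you mean '{hint[0]}'?)"
            errors.append(msg)
            continue
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        errors.append(f"{prefix}: {exc}")
        return cls()


def validate_config(raw) -> PipelineConfig:
    """Validate raw YAML text or a dict into a fully defaulted config.

    Unknown keys are rejected with a closest-match suggestion; value errors
    are aggregated into one message.
    """
    if isinstance(raw, (str, Path)):
        raw = yaml.safe_load(str(raw)) or {}
    if not isinstance(raw, dict):
        raise InputError("config must be a YAML mapping")
    errors: list[str] = []
    top = PipelineConfig.__dataclass_fields__
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key not in top:
            hint = difflib.get_close_matches(key, list(top) + ["flank", "seed"], n=1)
            msg = f"unknown key '{key}'"
            if hint:
                msg += f" (did you mean '{hint[0]}'?)"
            errors.append(msg)
            continue
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                errors.append(f"'{key}' must be a mapping")
                continue
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, errors,
                                         key + ".")
        else:
            kwargs[key] = value
    cfg = PipelineConfig(**{k: v for k, v in kwargs.items() if k in top}) \
        if not errors else PipelineConfig()
    if errors:
        raise InputError("invalid config:\n  " + "\n  ".join(errors))
    if not 0 < cfg.classification.alpha < 1:
        raise InputError("invalid config:\n  classification.alpha must lie in (0, 1)")
    if not 0 < cfg.enrichment.alpha < 1:
        raise InputError("invalid config:\n  enrichment.alpha must lie in (0, 1)")
    if cfg.flank < 0:
        raise InputError("invalid config:\n  flank must be >= 0")
    if not cfg.synthetic:
        missing = [k for k in ("protein", "genome", "peaks")
                   if getattr(cfg.inputs, k) is None]
        if missing:
            raise InputError("invalid config:\n  real-input mode needs paths: "
                             + ", ".join(missing))
    # keep the nested generation/discovery settings on the one global seed
    cfg.synthetic_config.seed = stage_seed(cfg.seed, "simulate")
    cfg.discovery.seed = stage_seed(cfg.seed, "discover")
    cfg.synthetic_config.flank = cfg.flank
    return cfg


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def read_gene_bed(path) -> "pd.DataFrame":
    import pandas as pd
    rows = []
    with open(path) as fh:
        for i, raw in enumerate(fh):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            rows.append({"chrom": p[0], "start": int(p[1]), "end": int(p[2]),
                         "gene_id": p[3] if len(p) > 3 else f"gene_{i + 1}",
                         "gene_name": p[4] if len(p) > 4 else p[3],
                         "strand": p[5] if len(p) > 5 else "."})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    t0 = time.time()
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_COUNTERS},
        "stages": {},
        "outputs": {},
    }
    timings: dict[str, float] = {}

    def clock(stage):
        timings[stage] = time.time()

    def done(stage):
        timings[stage] = round(time.time() - timings[stage], 3)

    try:
        # ------------------------------------------------------ inputs
        clock("simulate")
        truth = None
        if config.synthetic:
            ds = make_dataset(config.synthetic_config, outdir / "synthetic")
            protein = read_fasta(ds.paths["protein"])["erm_like_fixture"]
            table = load_default_recognition_table()
            genome = ds.genome
            peaks = ds.peaks
            genes = read_gene_bed(ds.paths["genes"])
            negatives = ds.background_windows
            background = make_background_model(config.synthetic_config)
            truth = ds.truth
            manifest["synthetic"] = {"config_hash": config.synthetic_config.config_hash()}
        else:
            import pyfaidx
            fasta = read_fasta(config.inputs.protein)
            rec_id = config.inputs.protein_id or next(iter(fasta))
            if rec_id not in fasta:
                raise InputError(f"protein record {rec_id!r} not in FASTA")
            protein = fasta[rec_id]
            table = (RecognitionTable.from_tsv(config.inputs.recognition_table)
                     if config.inputs.recognition_table
                     else load_default_recognition_table())
            genome = pyfaidx.Fasta(config.inputs.genome)
            peaks = read_bed(config.inputs.peaks)
            genes = (read_gene_bed(config.inputs.genes)
                     if config.inputs.genes else None)
            negatives = None
            background = None
        done("simulate")

        # ------------------------------------------------------ fingers
        clock("fingers")
        fingers = extract_zinc_fingers(protein)
        if not fingers:
            raise InputError("no C2H2 zinc fingers found in the protein")
        finger_pwms = [finger_to_pwm(f, table) for f in fingers]
        finger_consensi = [consensus(p) for p in finger_pwms]
        write_meme(finger_pwms, outdir / "fingers.meme")
        manifest["stages"]["fingers"] = {
            "n_fingers": len(fingers),
            "consensi": finger_consensi,
        }
        done("fingers")

        # ------------------------------------------------------ windows
        clock("windows")
        window_pairs, dropped = extract_windows(peaks, genome, config.flank)
        regions = [r for r, _ in window_pairs]
        windows = [s for _, s in window_pairs]
        if background is None:
            background = BackgroundModel.from_sequences(windows, order=0)
        manifest["stages"]["windows"] = {"n_windows": len(windows),
                                         "n_dropped": len(dropped)}
        done("windows")

        # ------------------------------------------------------ enrichment
        clock("enrich")
        ereports = []
        for cons, pwm in zip(finger_consensi, finger_pwms):
            rep = kmer_preference_enrichment(
                windows, cons, background,
                n_null=config.enrichment.n_null,
                seed=stage_seed(config.seed, "enrich"))
            ereports.append(rep)
        enriched_idx = [i for i, r in enumerate(ereports)
                        if r.fold > 1 and r.pvalue < config.enrichment.alpha]
        with open(outdir / "enrichment.tsv", "w") as fh:
            fh.write("finger\tpreference\tobserved\texpected\tfold\tpvalue\t"
                     "method\tenriched\n")
            for i, r in enumerate(ereports):
                fh.write(f"{i + 1}\t{r.preference}\t{r.observed}\t"
                         f"{r.expected:.2f}\t{r.fold:.3f}\t{r.pvalue:.3g}\t"
                         f"{r.method}\t{i in enriched_idx}\n")
        # windows carrying any enriched preference feed motif discovery
        if enriched_idx:
            from .sequence_scan import _iupac_regex, reverse_complement
            pats = []
            for i in enriched_idx:
                c = finger_consensi[i]
                pats += [_iupac_regex(c), _iupac_regex(reverse_complement(c))]
            disc_windows = [w for w in windows
                            if any(p.search(w.upper()) for p in pats)]
        else:
            disc_windows = list(windows)
        if not disc_windows:
            disc_windows = list(windows)
        manifest["stages"]["enrich"] = {
            "enriched_fingers": [i + 1 for i in enriched_idx],
            "n_discovery_windows": len(disc_windows),
        }
        done("enrich")

        # ------------------------------------------------------ discovery
        clock("discover")
        motif, disc_manifest = discover(disc_windows, config.discovery,
                                        background=background)
        write_meme([motif.pwm], outdir / "motif.meme",
                   background=background.marginals)
        (outdir / "discovery.yaml").write_text(
            yaml.safe_dump(disc_manifest, sort_keys=True))
        manifest["stages"]["discover"] = {
            "width": motif.width, "consensus": motif.consensus(),
            "occurrence_prior": round(motif.occurrence_prior, 4),
        }
        done("discover")

        # ------------------------------------------------------ classification
        clock("classify")
        cls = config.classification
        scores = score_regions(windows, motif, background)
        rng_null = np.random.default_rng(stage_seed(config.seed, "null"))
        if config.synthetic:
            null_windows = background.sample(cls.n_null, len(windows[0]), rng_null)
        else:
            null_windows = shuffled_null_windows(windows, cls.n_null,
                                                 stage_seed(config.seed, "null"))
        null_scores = score_regions(null_windows, motif, background)
        calib, calls = calibrate_fdr(scores, null_scores, cls.alpha,
                                     cls.fdr_method)
        if negatives is None:
            negatives = shuffled_null_windows(windows, len(windows),
                                              stage_seed(config.seed, "null") + 1)
        neg_scores = score_regions(negatives, motif, background)
        auc = compute_auc(scores, neg_scores)
        null_sample = random_motif_null(motif.width, cls.n_random_motifs,
                                        windows, negatives, background,
                                        seed=stage_seed(config.seed, "random_motifs"))
        if cls.control_motif:
            control = read_meme(cls.control_motif)[0]
        else:
            control = column_shuffled_control(
                motif.pwm, seed=stage_seed(config.seed, "control"))
        control_report = compare_negative_control(motif, control, windows,
                                                  negatives, null_sample,
                                                  background)

        called_regions = [r for r, c in zip(regions, calls) if c]
        with open(outdir / "calls.bed", "w") as fh:
            for r, s, c in zip(regions, scores, calls):
                if c:
                    fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\t"
                             f"{int(round(s * 100))}\t.\n")
        with open(outdir / "calls.tsv", "w") as fh:
            fh.write("region_id\tbest_score_bits\tcalled\tthreshold_bits\talpha\n")
            for r, s, c in zip(regions, scores, calls):
                fh.write(f"{r.id}\t{s:.4f}\t{c}\t{calib.threshold:.4f}\t"
                         f"{cls.alpha:g}\n")

        # distance histogram over called windows' best hits
        occurrences = []
        for r, w, c in zip(regions, windows, calls):
            if not c:
                continue
            occ, _ = scan_pwm(w, motif.pwm, background, region_id=r.id)
            occurrences.extend(occ)
        hist = peak_motif_distance_distribution(occurrences,
                                                range_bp=config.flank)
        hist.to_csv(outdir / "distance_histogram.tsv", sep="\t", index=False)

        report = {
            "n_windows": len(windows),
            "n_called": int(calls.sum()),
            "alpha": cls.alpha,
            "fdr_method": calib.method,
            "threshold_bits": calib.threshold if np.isfinite(calib.threshold) else None,
            "n_null": calib.n_null,
            "auc": auc,
            "auc_framing": "positives = peak windows, negatives = "
                           + ("generator background windows" if config.synthetic
                              else "dinucleotide-shuffled peak windows")
                           + "; score = best log-odds hit on either strand",
            "random_auc_mean": null_sample["mean"],
            "random_auc_sd": null_sample["sd"],
            "random_auc_n": null_sample["n"],
            "auc_percentile_in_null": control_report["auc_percentile"],
            "control_auc": control_report["control_auc"],
            "control_within_null": control_report["control_within_null"],
            "seed": config.seed,
        }
        if truth is not None:
            planted = truth["planted"].to_numpy()
            id_order = {r.id: i for i, r in enumerate(regions)}
            planted_mask = np.zeros(len(regions), dtype=bool)
            for wid, fl in zip(truth["window_id"], planted):
                if wid in id_order:
                    planted_mask[id_order[wid]] = bool(fl)
            tp = int((calls & planted_mask).sum())
            report["truth_recall"] = tp / max(1, int(planted_mask.sum()))
            report["truth_precision"] = tp / max(1, int(calls.sum()))
        (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                       sort_keys=True))
        manifest["stages"]["classify"] = {k: report[k] for k in
                                          ("n_called", "auc", "random_auc_mean")}
        done("classify")

        # ------------------------------------------------------ annotation
        clock("annotate")
        if genes is not None and len(genes):
            table_out = annotate_sites_to_genes(called_regions, genes,
                                                cls.max_gene_distance)
            with open(outdir / "gene_table.tsv", "w") as fh:
                fh.write("site_id\tCG_number\tgene_name\tdistance\n")
                for _, row in table_out.rows.iterrows():
                    fh.write(f"{row.site_id}\t{row.gene_id}\t{row.gene_name}\t"
                             f"{row.distance}\n")
            manifest["stages"]["annotate"] = {
                "n_annotated": len(table_out.rows),
                "n_unique_genes": len(table_out.unique_genes),
                "n_unassigned": table_out.n_unassigned,
            }
        done("annotate")
    except Exception:
        manifest["failed"] = True
        (outdir / "manifest.yaml").write_text(
            yaml.safe_dump(manifest, sort_keys=True))
        raise

    for name in sorted(p.name for p in outdir.glob("*")
                       if p.is_file() and p.name != "manifest.yaml"):
        manifest["outputs"][name] = _sha256(outdir / name)
    if config.synthetic:
        for name in sorted(p.name for p in (outdir / "synthetic").glob("*")):
            manifest["outputs"]["synthetic/" + name] = _sha256(
                outdir / "synthetic" / name)
    manifest["timings_s"] = timings
    manifest["total_s"] = round(time.time() - t0, 3)
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest
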