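"""End-to-end pipeline: simulate -> estimate -> process -> calibrate.

A :class:`PipelineConfig` (JSON or YAML on disk) fully determines one run:
genome, engineered pairs, polymer model, imaging settings, Hi-C settings,
titration ratios and one global seed.  The global seed is expanded into
per-stage seeds with ``numpy.random.SeedSequence(seed).spawn`` in a fixed
stage order, so every output is a pure function of the config.  The summary
JSON embeds a hash of the canonical config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import (
    CalibrationPoint,
    average_intra_slope,
    detection_limit,
    fit_linear,
    signal_to_frequency,
    slope_bias_test,
)
from .hicops import (
    distance_decay,
    junction_signal,
    kr_balance,
    merge_replicates,
    normalize_to_smallest,
    restriction_site_correction,
)
from .hicsim import JunctionSpec, simulate_hic
from .imaging import continuous_contact_frequency
from .loci import LocusPair
from .matrix import GenomeBins
from .polymer import PolymerModel
from .population import mix_populations, sample_population
from .timelapse import simulate_timelapse, write_tracks

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

_STAGES = ("populations", "imaging", "hic", "detection")


@dataclass
class PipelineConfig:
    chromsizes: dict[str, int]
    pairs: list[dict]  # pair_id, chrom_a, pos_a, chrom_b, pos_b
    bin_size: int = 10_000
    polymer: dict = field(default_factory=dict)  # PolymerModel kwargs
    p_plus: float = 0.65
    p_minus: float = 0.02
    ratios: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    n_cells: int = 2000
    n_frames: int = 3
    interval_s: float = 240.0
    tau_s: float = 60.0
    loc_noise_nm: float = 50.0
    detect_prob: float = 0.9
    threshold_um: float = 0.4
    k_frames: int = 3
    n_contacts: int = 18_000_000
    bias_sd: float = 0.2
    mean_sites_per_bin: float = 39.0
    n_hic_replicates: int = 2
    half_window_bp: float = 15_000
    detection_p_grid: tuple = (0.02, 0.05, 0.10, 0.20)
    detection_n_reps: int = 10
    run_detection: bool = True
    write_matrices: bool = False
    seed: int = 1

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def canonical_json(self) -> str:
        data = asdict(self)
        data["ratios"] = list(self.ratios)
        data["detection_p_grid"] = list(self.detection_p_grid)
        return json.dumps(data, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]

    def locus_pairs(self) -> list[LocusPair]:
        return [
            LocusPair(p["pair_id"], p["chrom_a"], int(p["pos_a"]), p["chrom_b"], int(p["pos_b"]))
            for p in self.pairs
        ]

    def model(self) -> PolymerModel:
        return PolymerModel(**self.polymer)

    def stage_seeds(self) -> dict[str, np.random.SeedSequence]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return dict(zip(_STAGES, children))


def validate_config(config: PipelineConfig) -> list[str]:
    """Cross-field validation; returns the aggregated list of error strings."""
    errors: list[str] = []
    if not config.chromsizes:
        errors.append("chromsizes: empty genome")
    if config.bin_size <= 0:
        errors.append("bin_size: must be positive")
    if config.seed is None or config.seed < 0:
        errors.append("seed: must be a non-negative integer")
    for p in (config.p_plus, config.p_minus):
        if not 0.0 <= p <= 1.0:
            errors.append(f"loop fraction {p}: outside [0, 1]")
    for r in config.ratios:
        if not 0.0 <= r <= 1.0:
            errors.append(f"ratio {r}: outside [0, 1]")
    try:
        model = config.model()
    except (TypeError, ValueError) as exc:
        errors.append(f"polymer: {exc}")
        model = None
    for spec in config.pairs:
        missing = {"pair_id", "chrom_a", "pos_a", "chrom_b", "pos_b"} - set(spec)
        if missing:
            errors.append(f"pair {spec.get('pair_id', '?')}: missing fields {sorted(missing)}")
            continue
        for side in ("a", "b"):
            chrom, pos = spec[f"chrom_{side}"], int(spec[f"pos_{side}"])
            if chrom not in config.chromsizes:
                errors.append(f"pair {spec['pair_id']}: unknown chromosome {chrom}")
            elif not 0 <= pos < config.chromsizes[chrom]:
                errors.append(f"pair {spec['pair_id']}: position {chrom}:{pos} beyond chromosome end")
    if config.n_cells < 1:
        errors.append("n_cells: must be >= 1")
    if config.n_contacts < 1:
        errors.append("n_contacts: must be >= 1")
    return errors


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full simulate -> estimate -> calibrate pipeline.

    Writes intermediate tables and a machine-readable ``summary.json`` under
    ``outdir`` and returns the summary dict.  Deterministic given the config.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    pairs = config.locus_pairs()
    model = config.model()
    intra_ids = [p.pair_id for p in pairs if p.is_intra]
    inter_ids = [p.pair_id for p in pairs if not p.is_intra]

    # --- stage 1+2: populations, mixtures, imaging estimates ----------------
    logger.info("stage imaging: %d pairs x %d ratios", len(pairs), len(config.ratios))
    pop_seeds = seeds["populations"].spawn(len(pairs))
    img_seeds = seeds["imaging"].spawn(len(pairs))
    estimates: dict[str, dict[float, dict]] = {}
    for pair, pseed, iseed in zip(pairs, pop_seeds, img_seeds):
        sub = pseed.spawn(2 + len(config.ratios))
        plus = sample_population(pair, config.p_plus, config.n_cells, model, _seed_int(sub[0]))
        minus = sample_population(pair, config.p_minus, config.n_cells, model, _seed_int(sub[1]))
        isub = iseed.spawn(len(config.ratios))
        estimates[pair.pair_id] = {}
        for k, ratio in enumerate(config.ratios):
            mixed = mix_populations(plus, minus, ratio, _seed_int(sub[2 + k]))
            tracks = simulate_timelapse(
                mixed,
                n_frames=config.n_frames,
                interval_s=config.interval_s,
                tau_s=config.tau_s,
                loc_noise_nm=config.loc_noise_nm,
                detect_prob=config.detect_prob,
                seed=_seed_int(isub[k]),
            )
            est = continuous_contact_frequency(
                tracks, threshold_um=config.threshold_um, k_frames=config.k_frames
            )
            estimates[pair.pair_id][ratio] = {"true_p": mixed.true_p, **est.to_dict()}
            if config.write_matrices:
                write_tracks(tracks, outdir / f"tracks_{pair.pair_id}_r{ratio:g}.tsv")
    (outdir / "imaging_estimates.json").write_text(json.dumps(estimates, indent=2))

    # --- stage 3: Hi-C simulation, processing, junction signals -------------
    logger.info("stage hic: %d libraries", len(pairs) * len(config.ratios) * config.n_hic_replicates)
    bins = GenomeBins(config.chromsizes, config.bin_size).with_poisson_sites(
        config.mean_sites_per_bin, _seed_int(seeds["hic"])
    )
    hic_seeds = seeds["hic"].spawn(len(pairs))
    points_by_pair: dict[str, list[CalibrationPoint]] = {}
    zero_matrices = {}
    for pair, hseed in zip(pairs, hic_seeds):
        sub = iter(hseed.spawn(len(config.ratios) * config.n_hic_replicates))
        raw = {
            ratio: [
                simulate_hic(
                    bins,
                    [JunctionSpec(pair, ratio * config.p_plus + (1 - ratio) * config.p_minus)],
                    model,
                    config.n_contacts,
                    config.bias_sd,
                    seed=_seed_int(next(sub)),
                )
                for _ in range(config.n_hic_replicates)
            ]
            for ratio in config.ratios
        }
        flat = [m for reps in raw.values() for m in reps]
        normed = normalize_to_smallest(flat)
        processed = []
        for m in normed:
            m = restriction_site_correction(m)
            kr_balance(m)
            processed.append(m)
        it = iter(processed)
        proc = {ratio: [next(it) for _ in range(config.n_hic_replicates)] for ratio in config.ratios}
        zero_matrices[pair.pair_id] = proc[min(config.ratios)]
        bg_signals = [
            junction_signal(m, pair, config.half_window_bp, use_weights=True)
            for m in proc[min(config.ratios)]
        ]
        s0 = float(np.mean(bg_signals))
        pts = []
        for ratio in config.ratios:
            f = estimates[pair.pair_id][ratio]["p_hat"]
            for rep, m in enumerate(proc[ratio]):
                s = junction_signal(m, pair, config.half_window_bp, use_weights=True)
                pts.append(
                    CalibrationPoint(
                        pair_id=pair.pair_id,
                        replicate_id=rep,
                        contact_frequency=f,
                        signal=s,
                        background_signal=s0,
                    )
                )
        points_by_pair[pair.pair_id] = pts

    # --- stage 4: calibration fits, slope ratio, conversion curve -----------
    fits = [fit_linear(pts) for pts in points_by_pair.values()]
    mean_intra = average_intra_slope(fits, intra_ids)
    ratio_stat = None
    if inter_ids:
        ratio, ci = slope_bias_test(fits, intra_ids, inter_ids, points_by_pair, seed=_seed_int(seeds["hic"]))
        ratio_stat = {"inter_over_intra": ratio, "ci95": ci}

    exclusions = [
        (p.chrom_a, p.pos_a - 50_000, p.pos_a + 50_000) for p in pairs
    ] + [(p.chrom_b, p.pos_b - 50_000, p.pos_b + 50_000) for p in pairs]
    intra_zero = [m for pid in intra_ids for m in zero_matrices[pid]]
    merged = merge_replicates(
        [m.copy_with(weights=None) for m in normalize_to_smallest(intra_zero)]
    )
    kr_balance(merged)
    decay = distance_decay(merged, exclusion_windows=exclusions, use_weights=True)
    decay["contact_frequency"] = signal_to_frequency(
        decay["mean_signal"].to_numpy(), mean_intra
    )
    # through-origin conversion is the default; the intercept-subtracting
    # variant is reported alongside so the offset is visible to the user
    mean_intercept = float(np.mean([f.intercept for f in fits if f.pair_id in intra_ids]))
    decay["contact_frequency_intercept_mode"] = signal_to_frequency(
        decay["mean_signal"].to_numpy(), mean_intra, intercept=mean_intercept
    )
    decay.to_csv(outdir / "contact_frequency_vs_distance.tsv", sep="\t", index=False)

    # --- stage 5: detection power analysis ----------------------------------
    det = None
    if config.run_detection:
        logger.info("stage detection: grid %s", config.detection_p_grid)
        intra_pair = next(p for p in pairs if p.is_intra)
        limit, report = detection_limit(
            bins,
            intra_pair,
            model,
            config.detection_p_grid,
            n_contacts=config.n_contacts,
            n_reps=config.detection_n_reps,
            bias_sd=config.bias_sd,
            seed=_seed_int(seeds["detection"]),
            half_window_bp=config.half_window_bp,
        )
        det = {"limit": limit, "detected_reps": {str(k): v for k, v in report.items()}}

    summary = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "imaging_estimates": estimates,
        "calibration_points": {
            pid: [asdict(p) for p in pts] for pid, pts in points_by_pair.items()
        },
        "fits": {f.pair_id: f.to_dict() for f in fits},
        "mean_intra_slope": mean_intra,
        "slope_bias": ratio_stat,
        "detection": det,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
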