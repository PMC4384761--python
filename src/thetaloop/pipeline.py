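"""End-to-end driver: simulate → detect → analyze → bootstrap.

A RunConfig bundles the generator, detector, behavior and analysis
settings plus one master seed; per-stage seeds are spawned from it in a
fixed order (lfp, behavior, bootstrap) so each stage is independently
reproducible.  ``run_pipeline`` writes every artifact with a content hash
into an append-only manifest, so two runs with the same config and seed
produce identical manifests.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import behavior_stats, io, phase_metrics, spectral
from .behavior_sim import BehaviorParams, simulate_cohort
from .closed_loop import DetectorConfig, run_closed_loop
from .synthetic_lfp import LfpGenConfig, generate_lfp

__all__ = ["AnalysisConfig", "RunConfig", "run_pipeline", "spawn_seeds"]

DEFAULT_BANDS = {
    "theta": (4.0, 12.0),
    "beta": (16.0, 25.0),
    "low_gamma": (25.0, 50.0),
    "high_gamma": (60.0, 80.0),
}
# a narrower low-gamma preset is sometimes used for stimulation sessions
LOW_GAMMA_NARROW = (25.0, 35.0)


@dataclass
class AnalysisConfig:
    alpha: float = 0.05
    n_boot: int = 10000
    consistency: int = 3
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    lfp_duration_s: float = 60.0
    psd_segment_s: float = 1.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not (0 < lo < hi):
                raise ValueError(f"band {name!r} edges must be positive and ordered")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


@dataclass
class RunConfig:
    lfp: LfpGenConfig = field(default_factory=LfpGenConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        zones = d.get("detector", {}).get("zone_intervals")
        if zones is not None:
            d["detector"]["zone_intervals"] = [tuple(z) for z in zones]
        bands = d.get("analysis", {}).get("bands")
        if bands is not None:
            d["analysis"]["bands"] = {k: tuple(v) for k, v in bands.items()}
        return cls(
            lfp=LfpGenConfig(**d.get("lfp", {})),
            detector=DetectorConfig(**d.get("detector", {})),
            behavior=BehaviorParams(**d.get("behavior", {})),
            analysis=AnalysisConfig(**d.get("analysis", {})),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        def norm(obj):
            if isinstance(obj, dict):
                return {k: norm(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [norm(v) for v in obj]
            return obj
        return norm(asdict(self))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def spawn_seeds(seed: int, n: int = 3) -> list[int]:
    """Stable per-stage integer seeds (< 2**31) derived from the master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full chain and return the manifest of produced files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_lfp, seed_behavior, seed_boot = spawn_seeds(config.seed)
    produced: list[Path] = []
    stage = "setup"
    try:
        # --- behavior ------------------------------------------------------
        stage = "simulate-behavior"
        params = config.behavior.with_(seed=seed_behavior)
        trials = simulate_cohort(params, seed=seed_behavior)
        trials_path = outdir / "trials.csv"
        io.write_trials(trials, trials_path)
        produced.append(trials_path)

        # --- LFP + closed loop --------------------------------------------
        stage = "simulate-lfp"
        lfp_cfg = config.lfp.with_(seed=seed_lfp)
        duration = config.analysis.lfp_duration_s
        baseline = generate_lfp(lfp_cfg, duration)
        produced.append(outdir / "signal_baseline.bin")
        io.write_signal(baseline, outdir / "signal_baseline")
        produced.append(outdir / "signal_baseline.json")

        stage = "detect"
        pulse_trains = {}
        for mode in ("peak", "trough"):
            det = config.detector.with_(mode=mode)
            train = run_closed_loop(baseline, det)
            pulse_trains[mode] = train
            p = outdir / f"pulses_{mode}.csv"
            io.write_pulses(train, p, zone_id="all")
            produced.append(p)
            stim = generate_lfp(lfp_cfg, duration, pulses=train)
            io.write_signal(stim, outdir / f"signal_{mode}")
            produced.extend([outdir / f"signal_{mode}.bin",
                             outdir / f"signal_{mode}.json"])

        # --- phase / spectral analysis --------------------------------------
        stage = "analyze"
        phase = phase_metrics.offline_phase(baseline)
        summary = {}
        for mode, train in pulse_trains.items():
            circ = phase_metrics.pulse_phases(train, phase)
            delays = phase_metrics.pulse_delays(train, phase)
            summary[mode] = {
                "n_pulses": len(train),
                "phase_mean_deg": circ.mean_deg, "phase_sd_deg": circ.sd_deg,
                "delay_mean_ms": delays.mean_ms, "delay_sd_ms": delays.sd_ms,
            }
        landmark = phase_metrics.highgamma_landmark(
            baseline, phase, pulses_by_mode=pulse_trains,
            band=config.analysis.bands["high_gamma"])
        summary["high_gamma_landmark_deg"] = landmark.landmark_deg
        summary["high_gamma_modulated"] = landmark.modulated
        phase_path = outdir / "phase_summary.json"
        io.write_json(summary, phase_path)
        produced.append(phase_path)

        seg_n = int(config.analysis.psd_segment_s * baseline.fs)
        from .core import SignalTrace
        segments = [SignalTrace(baseline.samples[i:i + seg_n], baseline.fs)
                    for i in range(0, len(baseline) - seg_n + 1, seg_n)]
        psd = spectral.multitaper_psd(segments)
        psd_path = outdir / "psd_baseline.csv"
        io.write_psd(psd, psd_path)
        produced.append(psd_path)

        stim_trace = io.read_signal(outdir / "signal_peak")
        evoked = spectral.evoked_average(stim_trace, pulse_trains["peak"].onsets)
        evoked_path = outdir / "evoked_peak.csv"
        io.write_evoked(evoked, evoked_path)
        produced.append(evoked_path)

        stage = "behavior-stats"
        acc = behavior_stats.summarize_accuracy(trials, alpha=config.analysis.alpha)
        types = behavior_stats.classify_trial_types(trials)
        summary_path = outdir / "summary.json"
        io.write_json({
            "accuracy": acc.table.to_dict(orient="records"),
            "group_means_pct": {f"{c}/{s}": v
                                for (c, s), v in acc.group_means().items()},
            "trial_types": types.table.to_dict(orient="records"),
        }, summary_path)
        produced.append(summary_path)

        stage = "bootstrap"
        dd = behavior_stats.double_dissociation_bootstrap(
            trials, n_boot=config.analysis.n_boot, alpha=config.analysis.alpha,
            consistency=config.analysis.consistency, seed=seed_boot)
        dd_path = outdir / "dd.json"
        io.write_json({
            "p_any_diagonal": dd.p_any_diagonal,
            "p_both_diagonals": dd.p_both_diagonals,
            "observed_hits": dd.observed_hits,
            "quadrants": {f"{c}/{s}": v for (c, s), v in dd.quadrants.items()},
            "n_boot": dd.n_boot, "alpha": dd.alpha,
        }, dd_path)
        produced.append(dd_path)
    except Exception as exc:
        _write_manifest(outdir, config, produced, failed_stage=stage, error=str(exc))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return _write_manifest(outdir, config, produced)


def _write_manifest(outdir: Path, config: RunConfig, produced,
                    failed_stage: str | None = None,
                    error: str | None = None) -> dict:
    entry = {
        "seed": config.seed,
        "config": config.to_dict(),
        "artifacts": [
            {"path": p.name, "sha256": _sha256(p)}
            for p in produced if p.exists()
        ],
    }
    if failed_stage is not None:
        entry["failed_stage"] = failed_stage
        entry["error"] = error
        entry["partial"] = True
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    else:
        manifest = {"runs": []}
    manifest["runs"].append(entry)
    manifest_path.write_text(json.dumps(manifest, indent=2))
    log = outdir / "run.log"
    with log.open("a") as fh:
        fh.write(json.dumps({"seed": config.seed,
                             "stage": failed_stage or "complete",
                             "n_artifacts": len(entry["artifacts"])}) + "\n")
    return entry
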