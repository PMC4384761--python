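#!/usr/bin/env python
"""High-gamma power as an absolute within-cycle phase landmark.

Bins the 60-80 Hz envelope by theta phase on baseline signal, locates the
landmark, and expresses each trigger mode's pulse phases relative to it.
Peak-triggered stimulation should precede the high-gamma peak and
trough-triggered stimulation should follow it.
"""
import argparse
from pathlib import Path

from thetaloop import highgamma_landmark, offline_phase
from thetaloop.io import read_pulses, read_signal, write_histogram, write_json

parser = argparse.ArgumentParser()
parser.add_argument("--lfp", type=Path, default=Path("results/lfp/baseline"))
parser.add_argument("--pulses", type=Path, default=Path("results/closed_loop"))
parser.add_argument("--outdir", type=Path, default=Path("results/landmark"))
args = parser.parse_args()

trace = read_signal(args.lfp)
phase = offline_phase(trace)
trains = {mode: read_pulses(args.pulses / f"pulses_{mode}.csv")
          for mode in ("peak", "trough")}
result = highgamma_landmark(trace, phase, pulses_by_mode=trains)
args.outdir.mkdir(parents=True, exist_ok=True)

write_histogram(result.bin_centers_deg - 10.0, result.envelope_by_bin,
                args.outdir / "envelope_by_phase.csv")
summary = {"landmark_deg": result.landmark_deg, "modulated": result.modulated}
for mode, rel in result.relative_hist.items():
    write_histogram(rel["bin_centers_deg"] - 10.0, rel["counts"],
                    args.outdir / f"relative_phase_{mode}.csv")
    summary[f"{mode}_relative_mean_deg"] = rel["circ_mean_deg"]
write_json(summary, args.outdir / "landmark.json")

print(f"high-gamma landmark at theta phase {result.landmark_deg:.0f} deg "
      f"(modulated: {result.modulated})")
for mode, rel in result.relative_hist.items():
    side = "before" if rel["circ_mean_deg"] < 0 else "after"
    print(f"  {mode}-triggered pulses {side} the landmark "
          f"(mean {rel['circ_mean_deg']:.0f} deg)")
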