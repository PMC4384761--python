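#!/usr/bin/env python
"""Run the causal phase detector on the baseline LFP in both trigger modes.

Reports the end-to-end latency budget: measured extremum-to-pulse delay vs
the closed-form decomposition (filter phase delay + comparator samples +
processing latency), and writes the pulse logs.
"""
import argparse
from pathlib import Path

from thetaloop import (DetectorConfig, expected_detection_delay_ms,
                       offline_phase, pulse_delays, run_closed_loop)
from thetaloop.io import read_signal, write_pulses

parser = argparse.ArgumentParser()
parser.add_argument("--lfp", type=Path, default=Path("results/lfp/baseline"))
parser.add_argument("--outdir", type=Path, default=Path("results/closed_loop"))
args = parser.parse_args()

trace = read_signal(args.lfp)
phase = offline_phase(trace)
args.outdir.mkdir(parents=True, exist_ok=True)

for mode in ("peak", "trough"):
    det = DetectorConfig(mode=mode)
    train = run_closed_loop(trace, det)
    write_pulses(train, args.outdir / f"pulses_{mode}.csv", zone_id="all")
    stats = pulse_delays(train, phase)
    closed_form = expected_detection_delay_ms(det, freq=8.0, fs=trace.fs)
    print(f"{mode}-triggered: {len(train)} pulses, "
          f"delay {stats.mean_ms:.1f} ± {stats.sd_ms:.1f} ms "
          f"(closed form {closed_form:.1f} ms)")
print("reference measured latencies in vivo: 21.7 ± 7.2 (peak), "
      "21.3 ± 7.4 ms (trough)")
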