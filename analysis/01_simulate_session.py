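#!/usr/bin/env python
"""Generate a seeded synthetic polysomnography + photometry session.

Writes the session (CSV traces, JSON ground truth, config) under
results/session/ and prints a summary of its composition: state
fractions, spindle and movement counts.
"""

import argparse
from pathlib import Path

from spindlelab import io
from spindlelab import synthgen as sg


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--duration", type=float, default=3600.0)
    ap.add_argument("--out", type=str, default="scratch/session",
                    help="output directory (full traces are large; kept "
                         "out of results/ by default)")
    args = ap.parse_args()

    cfg = sg.SynthConfig(total_duration=args.duration, seed=args.seed)
    rec, gt = sg.generate_session(cfg, args.seed)
    out = Path(args.out)
    io.write_session(out, rec, gt, cfg)

    hyp = gt.hypnogram
    print(f"session: {args.duration:.0f} s, seed {args.seed} -> {out}")
    for state in sg.STATES:
        print(f"  {state:5s} fraction: {hyp.fraction(state):.3f}")
    print(f"  ground-truth spindles: {len(gt.spindle_intervals)}")
    print(f"  ground-truth movement bouts: {len(gt.movement_intervals)}")


if __name__ == "__main__":
    main()
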