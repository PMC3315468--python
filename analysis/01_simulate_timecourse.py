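#!/usr/bin/env python
"""Duplex-class kinetics of passive demethylation under a DNMT-inhibitor pulse.

Simulates a fully methylated promoter population through daily divisions
with drug-era inhibition and washout, and tabulates the unmethylated (U),
hemimethylated (H) and fully methylated (F) duplex fractions per day.  The
expected picture: hemimethylated duplexes dominate one doubling after the
pulse, then are diluted into symmetrically demethylated ones.
"""

import argparse
from pathlib import Path

from azanome.pipeline import RunConfig, simulate_stage
from azanome.synthetic_data import example_amplicon, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = RunConfig(out_dir=args.out, seed=args.seed)
    region = example_amplicon()
    sim = simulate_stage(cfg, region)
    table = sim["class_table"]
    write_table(table, args.out / "timecourse_classes.tsv", args.seed)

    print(table.to_string(index=False, float_format="%.3f"))
    d = table.set_index("day")
    peak_h = d["H"].idxmax()
    print(
        f"\nhemimethylated duplexes peak at day {peak_h} "
        f"({100 * d.loc[peak_h, 'H']:.0f}%), then dilute into symmetric "
        f"demethylation (U at day {d.index[-1]}: "
        f"{100 * d['U'].iloc[-1]:.0f}%)"
    )


if __name__ == "__main__":
    main()
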