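#!/usr/bin/env python
"""Planted-effect recovery study: the package's validation headline.

Repeats the full analysis chain over independently seeded default cohorts
and tabulates, per repetition, whether each planted effect is recovered
with the correct sign: reduced integrity, increased transmodal GFC,
positive dynamic-GFC-intensity slopes, reduced alpha power, increased
LZc, and (receptor-coupled cohorts) a slope-map-density correlation
above 0.5.  Writes results/08_recovery/recovery.tsv.
"""

import argparse
from pathlib import Path

from psyfusion.recovery import recovery_study


def main() -> int:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-runs", type=int, default=20)
    parser.add_argument("--out", type=str, default="results/08_recovery")
    args = parser.parse_args()

    table = recovery_study(master_seed=args.seed, n_runs=args.n_runs)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "recovery.tsv", sep="\t", index=False)

    print(f"{args.n_runs} repetitions at default effect sizes (n = 12 subjects):")
    for col, label in [
        ("ok_integrity", "within-network integrity reduced (>=5/7 networks)"),
        ("ok_transmodal_gfc", "transmodal GFC increased"),
        ("ok_top_lmm_slope", "dynamic GFC ~ intensity slope positive (TOP)"),
        ("ok_alpha", "alpha oscillatory power reduced"),
        ("ok_lzc", "LZc signal diversity increased"),
        ("ok_receptor", "receptor-density correlation > 0.5"),
    ]:
        n = int(table[col].sum())
        print(f"  {label:<50} {n}/{args.n_runs}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
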