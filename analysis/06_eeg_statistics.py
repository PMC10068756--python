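#!/usr/bin/env python
"""EEG cluster statistics: channel-space permutation and intensity coupling.

Runs the eeg_stats stage: per-band channel-cluster permutation contrasts
of drug vs placebo, the LZ channel contrast, and the per-epoch
EEG-intensity correlation clusters.  Outputs under results/06_eeg_stats/.
"""

import argparse
import json
from pathlib import Path

from psyfusion.pipeline import RunConfig, run_pipeline


def main() -> int:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=str, default="results/06_eeg_stats")
    parser.add_argument("--n-perm", type=int, default=1000)
    args = parser.parse_args()

    cfg = RunConfig(out_dir=args.out, seed=args.seed,
                    stages=("eeg", "eeg_stats"), waves=False,
                    n_permutations=args.n_perm)
    run_pipeline(cfg)

    clusters = json.loads((Path(args.out) / "clusters.json").read_text())
    print("condition contrasts (channel clusters):")
    for measure, summary in clusters["condition_clusters"].items():
        sig = [c for c in summary["clusters"] if c["p"] < 0.05]
        best = min((c["p"] for c in summary["clusters"]), default=1.0)
        print(f"  {measure:<6} {len(sig)} significant cluster(s), min p = {best:.4f}")
    print("intensity-correlation clusters:")
    for measure, summary in clusters["intensity_correlation_clusters"].items():
        sig = [c for c in summary["clusters"] if c["p"] < 0.05]
        print(f"  {measure:<6} {len(sig)} significant cluster(s)")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
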