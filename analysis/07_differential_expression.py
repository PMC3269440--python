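#!/usr/bin/env python
"""Differential expression before and after batch correction.

Runs the concordance study: replicate experiments share the same planted
group effects but draw independent batch noise; DE lists (|FC| >= 1.5 and
BH-adjusted p <= 0.01) are intersected across experiments before and after
empirical-Bayes correction by run.  Writes per-replicate counts to
results/diffexp/.
"""

import argparse
import json
from pathlib import Path

from batchscope.studies import concordance_study


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-reps", type=int, default=20)
    ap.add_argument("--out-dir", type=Path, default=Path("results/diffexp"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    study = concordance_study(seed=args.seed, n_reps=args.n_reps)
    (args.out_dir / "summary.json").write_text(
        json.dumps(study, indent=2, sort_keys=True) + "\n"
    )
    print(
        f"cross-experiment DE intersection grew after correction in "
        f"{100 * study['frac_improved']:.0f}% of {study['n_reps']} replicates "
        f"(mean common probes {study['mean_common_pre']:.1f} -> "
        f"{study['mean_common_post']:.1f})"
    )


if __name__ == "__main__":
    main()
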