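#!/usr/bin/env python
"""Generate the two canonical synthetic datasets.

1. A replicate-control experiment: one RNA source hybridised to every array
   of a balanced 3 experiments x 2 runs x 2 chips x 2 arrays design, with
   level SDs (0.30, 0.15, 0.10) and residual SD 0.20 on the log2 scale.
2. A paired-biopsy experiment: 14 duplicated tumour samples split across two
   runs, UHRR-like generic controls, and pre/post pooled controls, with
   expression coupling kappa = 0.5.

Artifacts (expression, detection, sample sheet, probe sheet/FASTA, truth
tables) are written under results/data/.
"""

import argparse
from pathlib import Path

from batchscope import io as bio
from batchscope.simulate import (
    replicate_control_design,
    simulate_experiment,
    tumour_duplicate_design,
)


def save(tag: str, out: Path, bundle) -> None:
    m, sheet, probes, truth = bundle
    d = out / tag
    d.mkdir(parents=True, exist_ok=True)
    bio.write_expression(m, d / "expression.tsv", d / "detection.tsv")
    bio.write_sample_sheet(sheet, d / "samples.tsv")
    bio.write_probe_sheet(probes, d / "probes.tsv")
    bio.write_probe_fasta(probes, d / "probes.fasta")
    truth.true_profiles.to_csv(d / "truth_profiles.tsv", sep="\t")
    truth.batch_shift.to_csv(d / "truth_batch_shift.tsv", sep="\t")
    print(f"[{tag}] {m.shape[0]} probes x {m.shape[1]} samples -> {d}")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--n-probes", type=int, default=1000)
    args = ap.parse_args()

    save("replicate_control", args.out_dir, simulate_experiment(
        replicate_control_design(n_probes=args.n_probes, seed=args.seed)
    ))
    save("tumour_duplicate", args.out_dir, simulate_experiment(
        tumour_duplicate_design(n_probes=args.n_probes, kappa=0.5,
                                seed=args.seed)
    ))


if __name__ == "__main__":
    main()
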