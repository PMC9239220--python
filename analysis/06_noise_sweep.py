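#!/usr/bin/env python
"""Channel comparison over 20 seeded studies: the noise-asymmetry result.

Repeats the full contextualization + prediction pipeline over independent
synthetic worlds and summarizes per-variant flux-prediction accuracy
against noiseless ground truth.  The question: does the low-noise
(accessibility-like) channel beat the high-noise (expression-like) one,
and where do the combinatory models land?
"""

import argparse
from pathlib import Path

from ymcflux.study import channel_comparison_study, summarize_by_model


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seeds", type=int, default=20, help="number of studies")
    parser.add_argument("--first-seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/noise_sweep"))
    args = parser.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    seeds = range(args.first_seed, args.first_seed + args.seeds)
    results = channel_comparison_study(seeds)
    results.to_csv(out / "per_phase_results.tsv", sep="\t", index=False)
    summary = summarize_by_model(results)
    summary.to_csv(out / "summary.tsv", sep="\t")

    print(f"{args.seeds} studies x {results['phase'].nunique()} phases, "
          "flux correlation vs noiseless ground truth:")
    print(summary.round(4))
    mean_r = summary["mean_r"]
    print(
        "low-noise channel beats high-noise channel:",
        bool(mean_r["atac"] > mean_r["rna"]),
        "| intersection beats high-noise channel:",
        bool(mean_r["intersection"] > mean_r["rna"]),
        "| every contextualized variant beats the generic model:",
        bool(mean_r[["rna", "atac", "intersection", "union"]].min() > mean_r["generic"]),
    )


if __name__ == "__main__":
    main()
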