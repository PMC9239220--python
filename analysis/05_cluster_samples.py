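#!/usr/bin/env python
"""Hierarchical clustering of the omics samples.

Clusters the replicate samples of both channels on Euclidean distances
between log2-transformed profiles (average linkage) — the data-analysis
step that checks whether samples group by phase before any model work.
"""

import argparse
import json
from pathlib import Path

from ymcflux.evaluation import hierarchical_cluster
from ymcflux.omics import read_omics


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/simulation"))
    parser.add_argument("--outdir", type=Path, default=Path("results/clustering"))
    args = parser.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    for channel in ("rna", "atac"):
        table = read_omics(args.indir / f"{channel}.tsv")
        result = hierarchical_cluster(table, method="average", log2=True)
        doc = {
            "samples": result.samples,
            "leaf_order": result.leaf_order,
            "linkage": result.linkage.tolist(),
        }
        (out / f"{channel}_dendrogram.json").write_text(json.dumps(doc, indent=1))
        phases = [s.rsplit("_", 1)[0] for s in result.leaf_order]
        grouped = all(
            phases[i] == phases[i + 1] for i in range(0, len(phases) - 1, 2)
        )
        print(f"{channel}: leaf order {result.leaf_order} "
              f"({'replicates group by phase' if grouped else 'replicates mix across phases'})")


if __name__ == "__main__":
    main()
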