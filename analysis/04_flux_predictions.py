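#!/usr/bin/env python
"""Flux predictions and their validation against measured fluxes.

Runs the two-stage FBA (growth maximization, then total-flux minimization
at 10% growth slack) on the generic model and the four context models of
every phase, compares each prediction with the phase's measured fluxes
(Pearson r, MSE), and tests channel differences with Fisher's z.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from ymcflux.evaluation import compare_fluxes, fisher_z_test, read_measured_fluxes
from ymcflux.gimme import GimmeConfig
from ymcflux.model import read_model
from ymcflux.omics import read_omics
from ymcflux.pipeline import run_phase
from ymcflux.synthetic import SyntheticSpec


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--indir", type=Path, default=Path("results/simulation"))
    parser.add_argument("--outdir", type=Path, default=Path("results/flux_predictions"))
    args = parser.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    spec = SyntheticSpec(seed=args.seed)
    model = read_model(args.indir / "model.json")
    rna = read_omics(args.indir / "rna_phase_means.tsv")
    atac = read_omics(args.indir / "atac_phase_means.tsv")

    rows = []
    comparisons = {}
    for phase in spec.phases:
        pm = run_phase(model, rna, atac, phase, GimmeConfig(), spec.simulation_config(phase))
        measured = read_measured_fluxes(args.indir / f"measured_{phase}.tsv")
        for name, flux in pm.fluxes.items():
            result = compare_fluxes(flux, measured)
            comparisons[(phase, name)] = result
            rows.append(
                {
                    "phase": phase,
                    "model": name,
                    "r": result.r,
                    "mse": result.mse,
                    "n": result.n,
                    "growth": flux.objective_value,
                    "v_opt": pm.results[name].v_opt,
                }
            )
            flux_rows = [{"reaction_id": r, "flux": flux[r]} for r in pm.models[name].reaction_ids]
            pd.DataFrame(flux_rows).to_csv(out / f"fluxes_{phase}_{name}.tsv", sep="\t", index=False)

    table = pd.DataFrame(rows)
    table.to_csv(out / "prediction_metrics.tsv", sep="\t", index=False)
    print("prediction performance (Pearson r vs measured fluxes):")
    print(table.pivot(index="model", columns="phase", values="r").round(3))

    z_tests = {}
    for phase in spec.phases:
        for name in ("atac", "intersection"):
            a, b = comparisons[(phase, name)], comparisons[(phase, "rna")]
            if a.r is None or b.r is None:
                continue
            z, p = fisher_z_test(a.r, a.n, b.r, b.n)
            z_tests[f"{phase}:{name}_vs_rna"] = {"z": z, "p": p, "significant": p < 0.05}
    (out / "fisher_z_tests.json").write_text(json.dumps(z_tests, indent=1))
    print("Fisher z comparisons vs the expression channel:")
    for key, value in z_tests.items():
        print(f"  {key}: z = {value['z']:+.3f}, p = {value['p']:.4f}")


if __name__ == "__main__":
    main()
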