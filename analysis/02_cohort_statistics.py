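#!/usr/bin/env python
"""Habitat statistics on the simulated cohort.

Runs the full cohort pipeline (spectra -> Bray-Curtis -> one-way PERMANOVA
-> PCA) on the proteomes written by 01_simulate_cohort.py, then trains and
evaluates the nearest-centroid habitat classifier on a fresh hold-out
cohort.  Key tables land in results/; full pipeline outputs under
scratch/cohort_run/.
"""

import json
from pathlib import Path

import pandas as pd

import piscape as ps
from piscape.pipeline import RunConfig, run_cohort_analysis
from piscape.spectrum import acid_neutral_basic

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data" / "cohort"
RUN = ROOT / "scratch" / "cohort_run"
RESULTS = ROOT / "results"
SEED = 1234


def main() -> None:
    metas = ps.read_metadata(DATA / "metadata.tsv")
    config = RunConfig(
        fasta_paths={m.proteome_id: str(DATA / f"{m.proteome_id}.faa")
                     for m in metas},
        metadata_path=str(DATA / "metadata.tsv"),
        output_dir=str(RUN),
        permanova_factors=("habitat",),
        n_permutations=999,
        seed=SEED,
    )
    results = run_cohort_analysis(config)
    res = results["permanova"]["habitat"]
    print(f"PERMANOVA (habitat): pseudo-F={res.pseudo_F:.2f} "
          f"R2={res.r_squared:.3f} p={res.p_value:.4g}")

    # hold-out classification: marine vs freshwater centroids
    refs: dict[str, list] = {}
    for meta in metas:
        refs.setdefault(meta.habitat, []).append(
            acid_neutral_basic(results["spectra"][meta.proteome_id]))
    holdout_specs = {h: ps.habitat_specs(n_proteins=300)[h]
                     for h in ("marine", "freshwater")}
    holdout, holdout_meta = ps.generate_cohort(10, holdout_specs,
                                               seed=SEED + 1)
    rows = []
    for meta in holdout_meta:
        pis = ps.isoelectric_points(
            [r.sequence for r in holdout[meta.proteome_id]])
        label, margin = ps.classify_habitat(ps.bin_spectrum(pis), refs)
        rows.append({"proteome_id": meta.proteome_id, "true": meta.habitat,
                     "predicted": label, "margin": round(margin, 4)})
    calls = pd.DataFrame(rows)
    accuracy = (calls["true"] == calls["predicted"]).mean()
    calls.to_csv(RESULTS / "classifier_holdout.tsv", sep="\t", index=False)

    summary = {"permanova_habitat": {"pseudo_F": res.pseudo_F,
                                     "r_squared": res.r_squared,
                                     "p_value": res.p_value},
               "classifier_holdout_accuracy": accuracy,
               "n_proteomes": results["n_proteomes"], "seed": SEED}
    (RESULTS / "cohort_statistics.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print(f"hold-out classifier accuracy: {accuracy:.2f} "
          f"({len(calls)} proteomes)")


if __name__ == "__main__":
    main()
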