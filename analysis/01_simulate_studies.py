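#!/usr/bin/env python
"""Generate synthetic binding studies for the four CysLTR1 ligands.

One study per ligand, using its reported binding parameters as ground
truth and its actual injection concentration grid, rendered as tailing
chromatogram text files under scratch/synthetic_studies/ (one directory
per ligand, with the metadata table and truth.json the downstream fit
script consumes). A small per-injection summary lands in results/.
"""

from pathlib import Path

import pandas as pd

from affinichrom import ColumnSystem, SimulationTruth, published
from affinichrom.pipeline import write_synthetic_study

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "synthetic_studies"
RESULTS = ROOT / "results"
SEED = 20240601


def main():
    RESULTS.mkdir(exist_ok=True)
    column = ColumnSystem(
        t0=published.VOID_TIME_MIN,
        flow_rate=published.BINDING_FLOW_ML_MIN,
        column_dims="4.6 x 30 mm",
    )
    rows = []
    for i, analyte in enumerate(published.ANALYTES):
        truth = SimulationTruth(
            K_A=published.REPORTED_K_A[analyte],
            n_a=published.REPORTED_N_A[analyte],
            column=column,
            rel_sd_tr=0.005,  # matches the column's repeatability RSD
            detector_sd=0.05,
            seed=SEED + i,
        )
        concs = [c * 1e-3 for c in published.CONCENTRATION_GRIDS_MM[analyte]]
        meta = write_synthetic_study(
            OUT / analyte,
            truth,
            concs,
            published.INJECTION_VOLUME_L,
            analyte=analyte,
        )
        table = pd.read_csv(meta)
        rows.append(
            {
                "analyte": analyte,
                "n_injections": len(table),
                "conc_min_mM": table.concentration_mM.min(),
                "conc_max_mM": table.concentration_mM.max(),
                "truth_K_A": truth.K_A,
                "truth_n_a": truth.n_a,
                "seed": truth.seed,
            }
        )
        print(f"{analyte}: {len(table)} injections written to {meta.parent}")
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "simulated_studies.csv", index=False)
    print(f"\nstudy summary -> {RESULTS / 'simulated_studies.csv'}")


if __name__ == "__main__":
    main()
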