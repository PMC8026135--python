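"""Simulate every input the downstream analyses consume.

Generates, with one seed: bulk thalamus/cortex counts for astrocytes and
neurons, bulk counts for the three sensory thalamic nuclei, a single-cell
matrix with QC covariates, a table of reporter-barcoded cells with known
clone structure, and ChIP/RT qPCR Ct tables with known enrichments.
Writes everything under results/data/ and prints what was made.

Usage: python analysis/01_simulate_inputs.py [--seed 1] [--out results]
"""

import argparse
from pathlib import Path

from regiosig.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed, stages=("simulate",))
    report = run_pipeline(cfg, args.out)
    sim = report["stages"]["simulate"]
    print(f"bulk Th/Ctx matrix: {sim['bulk_shape'][0]} genes x "
          f"{sim['bulk_shape'][1]} samples")
    print(f"bulk nuclei matrix: {sim['nuclei_shape'][0]} genes x "
          f"{sim['nuclei_shape'][1]} samples")
    print(f"single-cell matrix: {sim['sc_shape'][0]} genes x "
          f"{sim['sc_shape'][1]} cells")
    print(f"barcoded cells:     {sim['n_barcoded_cells']}")
    print(f"inputs written under {args.out / 'data'}")


if __name__ == "__main__":
    main()
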