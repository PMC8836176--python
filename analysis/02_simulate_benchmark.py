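"""Generate the synthetic benchmark dataset used by the downstream steps.

Writes a complete run directory (count matrices, condition labels,
transcript FASTA files, machine-readable ground truth) under
``results/benchmark/``. The design plants 3 sponge circuits among 50
decoy genes at 3 replicates per condition, NB dispersion 0.05, and
effect sizes (lncRNA +2.0, miRNA -1.5, mRNA +1.5) comfortably above the
detection boundary at n=3 (see docs/methods.md on power).

Run from the repository root: ``python analysis/02_simulate_benchmark.py [seed]``
"""

import sys
from pathlib import Path

from spongescan.pipeline import PipelineConfig, stage_simulate
from spongescan.simulate import SimulationDesign

OUT = Path("results/benchmark")


def design(seed: int) -> SimulationDesign:
    return SimulationDesign(seed=seed, lnc_log2fc=2.0, mir_log2fc=-1.5, mrna_log2fc=1.5)


def main(seed: int = 1653) -> None:
    cfg = PipelineConfig(outdir=str(OUT), seed=seed)
    stage_simulate(cfg, design(seed))
    d = design(seed)
    print(f"wrote {OUT}/: {d.n_lncrna} lncRNA + {d.n_mrna} mRNA gene counts, "
          f"{d.n_mirna} miRNA counts, {d.n_control}+{d.n_stimulated} samples, "
          f"{d.n_circuits} planted circuits (ground_truth.yaml), seed {seed}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1653)
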