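#!/usr/bin/env python
"""Generate the synthetic benchmark inputs with planted ground truth.

Writes the region x gene expression matrix, the per-subject connectivity
vectors, the network atlas and the truth record (planted coupling genes,
network-specific genes, connectivity template) under the run directory.
"""

from pathlib import Path

from _common import parse
from genefc.pipeline import run_full_pipeline

cfg = parse(__doc__)
manifest = run_full_pipeline(cfg, stages=("simulate",))
c = manifest.stages["simulate"]["counts"]
print(
    f"simulated {c['n_regions']} regions, {c['n_genes']} genes, "
    f"{c['n_subjects']} subjects -> {cfg.outdir}"
)
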