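#!/usr/bin/env python
"""Reliable genes and gene-related connections.

Permutation test on the population-averaged contributions (a gene is kept
only if its observed mean beats all 1000 shuffles), intersection with the
tensor-route genes, and the two-route connection selection (population
|CEC| mean+SD intersected with the leading component's connection weights).
"""

from _common import parse
from genefc.pipeline import run_full_pipeline

cfg = parse(__doc__)
manifest = run_full_pipeline(cfg, stages=("select",))
c = manifest.stages["select"]["counts"]
print(
    f"genes: tensor route {c['n_tensor_genes']}, permutation route "
    f"{c['n_permutation_genes']}, reliable (both) {c['n_reliable_genes']}"
)
print(
    f"connections: CEC route {c['n_cec_connections']}, tensor route "
    f"{c['n_tensor_connections']}, final {c['n_final_connections']} "
    f"(containment {c['tensor_route_containment']:.2f})"
)
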