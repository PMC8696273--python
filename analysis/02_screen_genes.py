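#!/usr/bin/env python
"""Individual-level screening of connectivity-related genes.

For every subject, each gene's co-expression product across region pairs is
correlated with that subject's connectivity; genes significant (Bonferroni)
in more than 80% of subjects form the connectivity-related gene pool.
"""

from _common import parse
from genefc.pipeline import run_full_pipeline

cfg = parse(__doc__)
manifest = run_full_pipeline(cfg, stages=("screen",))
c = manifest.stages["screen"]["counts"]
print(
    f"pool of {c['pool_size']} connectivity-related genes "
    f"(per-test threshold P < {c['p_threshold']:.3g}) -> pool.txt"
)
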