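"""Synthetic data with planted ground truth for the coupling pipeline.

The generator emulates the three inputs of the analysis — a region x gene
expression matrix, per-subject region x region functional connectivity, and
a region -> network atlas — with known planted structure so that every
downstream stage has a recovery test:

* a **connectivity template** elevated on within-network and homologous
  (left-right mirror) region pairs, shared by all subjects up to iid noise;
* **coupling genes**: with ``coupling_pattern="rank1"`` (default) every
  coupling gene follows the regional pattern ``v`` maximizing the
  correlation between the outer product ``v_i v_j`` and the template across
  connections — the expression pattern whose co-expression product best
  tracks a symmetric connectivity template (a single gene's product is
  rank-1 in (i, j), so this is the strongest planted signal possible);
  with ``coupling_pattern="bilateral"`` each coupling gene is an independent
  hemisphere-symmetric pattern (identical values on homolog pairs), so its
  co-expression tracks homotopic connectivity equally in every network —
  the archetype of a network-shared coupling gene;
* **network-specific genes** built from the leading eigenvector of the
  template restricted to one network's regions (zero elsewhere before
  noise), so their coupling contribution concentrates on that network's
  intra-network connections;
* background genes that are pure noise.

One expression matrix is shared by all subjects, matching the design of the
reference study (donor expression is constant across imaging subjects).
Generated connectivity lives on an unbounded template-plus-noise scale, so
downstream normalization should be run with ``fisher=False``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import NetworkAtlas, connection_pairs, n_connections, vector_to_square
from .coupling import (
    ConnectivitySet,
    ExpressionMatrix,
    normalize_connectivity,
    normalize_expression,
)

_HEMI = ("L", "R")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic benchmark.

    ``coupling_effect`` is the share of a planted gene's expression variance
    aligned with the connectivity template (0 = pure noise, 1 = noiseless).
    ``network_specific_map`` maps gene index -> network index for planted
    network-specific genes; coupling genes occupy indices
    ``0 .. n_coupling_genes-1`` and must not overlap it.
    """

    n_regions: int = 30
    n_genes: int = 300
    n_subjects: int = 40
    network_sizes: tuple = (14, 8, 4, 4)
    n_coupling_genes: int = 20
    coupling_effect: float = 0.5
    coupling_effect_spread: float = 0.0
    coupling_pattern: str = "rank1"
    specific_effect: float | None = None
    network_specific_map: dict = field(default_factory=dict)
    fc_base: float = 0.1
    system_assignment: tuple | None = None
    system_fc_boost: float = 0.5
    intra_network_fc_boost: float = 0.5
    homolog_fc_boost: float = 0.25
    subject_noise_sd: float = 0.2
    subject_noise_sd_spread: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling_pattern not in ("rank1", "bilateral"):
            raise ValueError("coupling_pattern must be 'rank1' or 'bilateral'")
        if sum(self.network_sizes) != self.n_regions:
            raise ValueError("network_sizes must sum to n_regions")
        if not 0.0 <= self.coupling_effect <= 1.0:
            raise ValueError("coupling_effect must lie in [0, 1]")
        lo = self.coupling_effect - self.coupling_effect_spread
        hi = self.coupling_effect + self.coupling_effect_spread
        if self.coupling_effect_spread < 0 or lo < 0 or hi > 1:
            raise ValueError("coupling_effect_spread must keep effects in [0, 1]")
        if self.subject_noise_sd_spread < 0 or (
            self.subject_noise_sd_spread > self.subject_noise_sd
        ):
            raise ValueError("subject_noise_sd_spread must keep noise SDs positive")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be non-negative")
        specific = set(self.network_specific_map)
        if specific & set(range(self.n_coupling_genes)):
            raise ValueError("network-specific genes overlap coupling genes")
        if self.n_coupling_genes + len(specific) > self.n_genes:
            raise ValueError("more planted genes than genes")
        if any(g < 0 or g >= self.n_genes for g in specific):
            raise ValueError("network_specific_map gene index out of range")
        n_net = len(self.network_sizes)
        if any(k < 0 or k >= n_net for k in self.network_specific_map.values()):
            raise ValueError("network_specific_map network index out of range")
        if self.specific_effect is not None and not 0 <= self.specific_effect <= 1:
            raise ValueError("specific_effect must lie in [0, 1]")
        if self.system_assignment is None:
            # hierarchical default: the first (largest) network forms one
            # system, the remaining networks the other
            self.system_assignment = (0,) + (1,) * (n_net - 1)
        if len(self.system_assignment) != n_net:
            raise ValueError("system_assignment needs one entry per network")

    def coupling_effects(self) -> np.ndarray:
        """Per-gene effect sizes for the planted coupling genes.

        Evenly spaced over ``coupling_effect +/- coupling_effect_spread``
        (a fixed, deterministic gradient of effect strength): real
        connectivity-related genes are not equally coupled, and the
        tensor/permutation selection stages specifically target the
        strongest of them.
        """
        n = self.n_coupling_genes
        if n == 0:
            return np.empty(0)
        if n == 1 or self.coupling_effect_spread == 0:
            return np.full(n, self.coupling_effect)
        return self.coupling_effect + self.coupling_effect_spread * np.linspace(
            -1.0, 1.0, n
        )

    @property
    def network_names(self) -> tuple:
        return tuple(f"net{k}" for k in range(len(self.network_sizes)))


def default_config(seed: int = 0) -> SyntheticConfig:
    """The standard benchmark: 90 regions (the reference atlas size, so all
    4005 connections) in 4 networks of heterogeneous size, 300 genes of
    which 20 globally coupled (rank-1 pattern, effect sizes 0.3-0.9) and 10
    network-specific, 40 subjects with heterogeneous noise levels."""
    return SyntheticConfig(
        n_regions=90,
        network_sizes=(42, 24, 12, 12),
        network_specific_map={20 + k: k % 4 for k in range(10)},
        coupling_effect=0.6,
        coupling_effect_spread=0.3,
        subject_noise_sd_spread=0.1,
        seed=seed,
    )


def dissection_config(seed: int = 0) -> SyntheticConfig:
    """Benchmark for network-level dissection: 40 regions in four equal
    networks of 10, 20 bilateral (network-shared) coupling genes and 10
    network-specific genes (effect 0.75) among 160 genes, 40 subjects.

    Equal network sizes make the homologous-connection share identical in
    every network, so bilateral genes have network-balanced contributions
    and are the planted ground truth for the network-shared ANOVA.
    """
    return SyntheticConfig(
        n_regions=40,
        n_genes=160,
        network_sizes=(10, 10, 10, 10),
        coupling_pattern="bilateral",
        network_specific_map={20 + k: k % 4 for k in range(10)},
        specific_effect=0.75,
        seed=seed,
    )


def connectivity_config(seed: int = 0) -> SyntheticConfig:
    """Benchmark for gene-related connection recovery: homotopic coupling.

    40 regions in four networks of 10 with a homotopic-dominated template
    (homolog boost 1.0 over intra-network 0.3), and 50 bilateral coupling
    genes (effect 0.7) among 150.  The ensemble of bilateral genes elevates
    co-expression at every homologous pair, so the planted gene-related
    connections are exactly the 20 homologous connections — the synthetic
    analogue of homotopic connectivity being the most strongly
    expression-coupled part of the connectome.
    """
    return SyntheticConfig(
        n_regions=40,
        n_genes=150,
        network_sizes=(10, 10, 10, 10),
        n_coupling_genes=50,
        coupling_effect=0.7,
        coupling_pattern="bilateral",
        system_fc_boost=0.0,
        intra_network_fc_boost=0.3,
        homolog_fc_boost=1.0,
        seed=seed,
    )


@dataclass
class SyntheticDataset:
    """Generated inputs plus the planted-truth record."""

    expression: ExpressionMatrix
    connectivity: ConnectivitySet
    atlas: NetworkAtlas
    truth: dict
    raw_expression: np.ndarray
    raw_connectivity: np.ndarray
    config: SyntheticConfig

    def write(self, outdir) -> dict:
        """Write the three inputs as TSV and the truth record as JSON."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.tsv",
            "connectivity": outdir / "connectivity.tsv",
            "atlas": outdir / "atlas.tsv",
            "truth": outdir / "truth.json",
        }
        pd.DataFrame(
            self.raw_expression,
            index=self.expression.region_ids,
            columns=self.expression.gene_ids,
        ).to_csv(paths["expression"], sep="\t", index_label="region_id")
        iu, ju = connection_pairs(self.atlas.n_regions)
        pd.DataFrame(
            self.raw_connectivity,
            index=self.connectivity.subject_ids,
            columns=[f"{i}_{j}" for i, j in zip(iu, ju)],
        ).to_csv(paths["connectivity"], sep="\t", index_label="subject_id")
        self.atlas.to_tsv(paths["atlas"])
        truth = dict(self.truth)
        truth["template"] = np.asarray(truth["template"]).tolist()
        truth["coupled_connections"] = [int(s) for s in truth["coupled_connections"]]
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1)
        return paths


def generate_atlas(config: SyntheticConfig) -> NetworkAtlas:
    """Atlas with interleaved left/right homologs (AAL-style).

    Regions ``2k`` and ``2k+1`` form a contralateral homolog pair and share
    a network label, so every network size must be even.
    """
    if config.n_regions % 2:
        raise ValueError("homolog pairing requires an even region count")
    if any(sz % 2 for sz in config.network_sizes):
        raise ValueError("every network size must be even for homolog pairing")
    rows = []
    region = 0
    for name, size in zip(config.network_names, config.network_sizes):
        for _ in range(size):
            hemi = _HEMI[region % 2]
            homolog = region + 1 if region % 2 == 0 else region - 1
            rows.append(
                {
                    "region_id": region,
                    "region_name": f"{name}_{region // 2}{hemi}",
                    "network": name,
                    "hemisphere": hemi,
                    "homolog_id": homolog,
                }
            )
            region += 1
    return NetworkAtlas(pd.DataFrame(rows), network_names=config.network_names)


def _template_vector(config: SyntheticConfig, atlas: NetworkAtlas) -> np.ndarray:
    iu, ju = connection_pairs(atlas.n_regions)
    nets = atlas.networks
    hom = atlas.homolog_ids
    net_pos = {name: k for k, name in enumerate(config.network_names)}
    systems = np.array([config.system_assignment[net_pos[n]] for n in nets])
    template = np.full(iu.shape, config.fc_base, dtype=float)
    same_sys = systems[iu] == systems[ju]
    same_net = nets[iu] == nets[ju]
    homologous = hom[iu] == ju
    template[same_sys] += config.system_fc_boost
    template[same_net] += config.intra_network_fc_boost
    template[homologous] += config.homolog_fc_boost
    return template


def generate_connectivity(
    config: SyntheticConfig, atlas: NetworkAtlas, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject raw connectivity vectors and the shared template.

    ``T_s = base + system_boost * [same system] + intra_boost * [same
    network] + homolog_boost * [homologs]`` and each subject is
    ``T + iid N(0, sigma_h^2)`` with a per-subject noise level drawn
    uniformly from ``subject_noise_sd +/- subject_noise_sd_spread``
    (individuals differ in data quality, hence in coupling strength).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    template = _template_vector(config, atlas)
    sigma = config.subject_noise_sd + config.subject_noise_sd_spread * rng.uniform(
        -1.0, 1.0, size=config.n_subjects
    )
    noise = rng.normal(0.0, 1.0, size=(config.n_subjects, template.size))
    fc = template[None, :] + sigma[:, None] * noise
    return fc, template


def _leading_eigvec(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    vec = v[:, -1]
    if vec.sum() < 0:  # fix sign for reproducibility
        vec = -vec
    return vec


def best_rank1_pattern(template: np.ndarray, n_regions: int) -> np.ndarray:
    """Regional pattern v maximizing |corr(v_i * v_j, T_ij)| over connections.

    A single gene's co-expression product is rank-1 in the region pair, so
    this is the strongest coupling signal a gene can carry for a given
    template.  Solved by BFGS from the doubly-centered template matrix's
    leading eigenvector (the classical relaxation of the problem);
    deterministic for a given template.
    """
    from scipy.optimize import minimize

    tmat = vector_to_square(template, n_regions)
    iu, ju = connection_pairs(n_regions)
    t_c = template - template.mean()
    t_norm = float(t_c @ t_c)
    if t_norm == 0:
        raise ValueError("degenerate (constant) connectivity template")

    def neg_abs_corr(v: np.ndarray) -> float:
        sd = v.std(ddof=0)
        if sd == 0:
            return 0.0
        v = (v - v.mean()) / sd  # evaluate on the standardized pattern
        p = v[iu] * v[ju]
        p_c = p - p.mean()
        denom = np.sqrt(float(p_c @ p_c) * t_norm)
        if denom == 0:
            return 0.0
        return -abs(float(p_c @ t_c)) / denom

    h = np.eye(n_regions) - 1.0 / n_regions
    b = h @ tmat @ h
    w, vecs = np.linalg.eigh(b)
    best_v, best_f = None, np.inf
    # few deterministic starts: top eigenvectors of the centered template
    for k in (1, 2, 3):
        v0 = vecs[:, -k]
        for v_start in (v0, -v0):
            res = minimize(neg_abs_corr, v_start, method="BFGS")
            cand = ((res.x, res.fun), (v_start, neg_abs_corr(v_start)))
            for v_c, f_c in cand:
                if f_c < best_f:
                    best_v, best_f = v_c, f_c
    v = best_v
    if v.sum() < 0:
        v = -v
    return v


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate (constant) template eigenvector")
    return (x - x.mean()) / sd


def generate_expression(
    config: SyntheticConfig,
    atlas: NetworkAtlas,
    template: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Raw region x gene expression with planted signal genes.

    Planted gene columns mix a standardized signal pattern with unit noise:
    ``sqrt(c_a) * v_a + sqrt(1-c_a) * noise`` with per-gene effect sizes
    from :meth:`SyntheticConfig.coupling_effects`.  Coupling genes use the
    best rank-1 template pattern (``rank1``) or independent
    hemisphere-symmetric patterns (``bilateral``); network-specific genes
    use the leading eigenvector of the template restricted to their
    network's regions, zero-padded elsewhere.  All columns are z-scored
    across regions on output.

    Returns the matrix and a record ``{gene_index: (effect, pattern)}`` of
    the planted signals (the basis of the connection-level ground truth).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    template = np.asarray(template, dtype=float)
    if template.shape != (n_connections(atlas.n_regions),):
        raise ValueError("template length inconsistent with atlas")
    if np.all(template == 0):
        raise ValueError("degenerate all-zero connectivity template")
    tmat = vector_to_square(template, atlas.n_regions)

    expr = rng.normal(0.0, 1.0, size=(atlas.n_regions, config.n_genes))
    signals: dict[int, tuple[float, np.ndarray]] = {}
    effects = config.coupling_effects()
    if config.n_coupling_genes:
        if config.coupling_pattern == "rank1":
            v_global = _standardize(best_rank1_pattern(template, atlas.n_regions))
            patterns = [v_global] * config.n_coupling_genes
        else:  # bilateral: per-gene hemisphere-symmetric pattern
            hom = atlas.homolog_ids
            patterns = []
            for _ in range(config.n_coupling_genes):
                v = rng.normal(size=atlas.n_regions)
                left = np.arange(atlas.n_regions) < hom  # first member of pair
                v[hom[left]] = v[left]
                patterns.append(_standardize(v))
        for a, (c, v) in enumerate(zip(effects, patterns)):
            expr[:, a] = np.sqrt(c) * v + np.sqrt(1 - c) * expr[:, a]
            signals[a] = (float(c), v)
    nets = atlas.networks
    c = (
        config.coupling_effect
        if config.specific_effect is None
        else config.specific_effect
    )
    for a, k in sorted(config.network_specific_map.items()):
        members = np.flatnonzero(nets == config.network_names[k])
        sub = tmat[np.ix_(members, members)]
        v_net = np.zeros(atlas.n_regions)
        v_net[members] = _leading_eigvec(sub)
        v_net = _standardize(v_net)
        expr[:, a] = np.sqrt(c) * v_net + np.sqrt(1 - c) * expr[:, a]
        signals[a] = (float(c), v_net)
    # z-score columns across regions (population SD)
    expr = (expr - expr.mean(0)) / expr.std(0, ddof=0)
    return expr, signals


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Compose atlas, connectivity and expression; pure function of config.

    The truth record carries the planted gene identities, the connectivity
    template, and ``coupled_connections``: the connections selected by the
    |CEC| > mean+SD rule in the noiseless limit (template connectivity and
    expected co-expression of the planted genes), i.e. the set a perfect
    run of the selection stage would recover.
    """
    rng = np.random.default_rng(config.seed)
    atlas = generate_atlas(config)
    fc_raw, template = generate_connectivity(config, atlas, rng)
    expr_raw, signals = generate_expression(config, atlas, template, rng)
    gene_ids = [f"g{a:04d}" for a in range(config.n_genes)]
    expression = normalize_expression(
        expr_raw, region_ids=list(range(config.n_regions)), gene_ids=gene_ids
    )
    connectivity = normalize_connectivity(fc_raw, config.n_regions, fisher=False)

    # noiseless-limit connection truth
    iu, ju = connection_pairs(config.n_regions)
    cge_expected = np.zeros(template.size)
    for a, (c, v) in signals.items():
        cge_expected += c * v[iu] * v[ju]

    def _z(x):
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    cec_true = np.abs(_z(template) * _z(cge_expected))
    sd_true = cec_true.std(ddof=1) if cec_true.size > 1 else 0.0
    if sd_true > 0:
        coupled = np.flatnonzero(cec_true > cec_true.mean() + sd_true)
    else:
        coupled = np.empty(0, dtype=int)

    truth = {
        "coupling_genes": gene_ids[: config.n_coupling_genes],
        "network_specific": {
            gene_ids[a]: config.network_names[k]
            for a, k in sorted(config.network_specific_map.items())
        },
        "template": template,
        "coupled_connections": coupled,
    }
    return SyntheticDataset(
        expression=expression,
        connectivity=connectivity,
        atlas=atlas,
        truth=truth,
        raw_expression=expr_raw,
        raw_connectivity=fc_raw,
        config=config,
    )
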