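"""Network-level dissection of connectivity-related genes.

Connections are classified as intra- or inter-network and as homologous
(left-right mirror pairs) from the atlas.  Gene-level dissection then runs
on the population-averaged coupling contributions C_sa restricted to
intra-network connections, grouped by network:

* **network-shared genes** — one-way ANOVA of a gene's C_sa across the
  network groups; genes with no significant difference (P >= 0.05) are
  common to all networks;
* **network-specific genes** — a four-criterion procedure: (1) the gene is
  selected by the mean+SD rule from the leading component of a CP
  decomposition restricted to the network's intra-network connections;
  (2) its specificity index (SI; target-network mean minus pooled
  other-network mean, adapted from cell-type specificity analysis) beats
  all label permutations; (3) ANOVA across the network groups rejects at a
  Bonferroni level scaled by the number of surviving candidates; and
  (4) the first-ranked network's mean contribution is at least twice the
  second's and a two-sample Welch t-test separates the two (P < 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import NetworkAtlas, connection_pairs
from .coupling import CouplingTensor
from .cpdecomp import (
    cp_decompose_seminonneg,
    select_leading_component,
    weight_threshold_select,
)


def classify_connections(atlas: NetworkAtlas) -> pd.DataFrame:
    """Per-connection classification table in canonical connection order.

    Columns: ``i``, ``j``, ``network_i``, ``network_j``, ``intra`` (both
    endpoints in the same network), ``network`` (the shared label for intra
    connections, empty otherwise) and ``homologous``.
    """
    iu, ju = connection_pairs(atlas.n_regions)
    nets = atlas.networks
    hom = atlas.homolog_ids
    intra = nets[iu] == nets[ju]
    return pd.DataFrame(
        {
            "i": iu,
            "j": ju,
            "network_i": nets[iu],
            "network_j": nets[ju],
            "intra": intra,
            "network": np.where(intra, nets[iu], ""),
            "homologous": hom[iu] == ju,
        }
    )


def intra_network_counts(classification: pd.DataFrame, network_names) -> pd.Series:
    """Number of intra-network connections per network (C(k, 2) for size k)."""
    intra = classification[classification["intra"]]
    counts = intra["network"].value_counts()
    return pd.Series({n: int(counts.get(n, 0)) for n in network_names})


def intra_network_report(
    classification: pd.DataFrame,
    selected: np.ndarray,
    network_names,
) -> pd.DataFrame:
    """Per-network accounting of selected intra-network connections.

    For each network: the number of intra-network connections, the number of
    those selected, ``A%`` (share of all selected intra-network connections)
    and ``B%`` (share of the network's own connections selected), plus a Sum
    row — the layout of the reference study's intra-network connection table.
    """
    selected = np.asarray(selected, dtype=bool)
    intra_counts = intra_network_counts(classification, network_names)
    sel_intra = classification["intra"].to_numpy() & selected
    sel_net = pd.Series(
        {
            n: int(
                (sel_intra & (classification["network"].to_numpy() == n)).sum()
            )
            for n in network_names
        }
    )
    total_sel = int(sel_net.sum())
    rows = []
    for n in network_names:
        rows.append(
            {
                "network": n,
                "n_intra_connections": int(intra_counts[n]),
                "n_selected": int(sel_net[n]),
                "A_pct": 100.0 * sel_net[n] / total_sel if total_sel else 0.0,
                "B_pct": 100.0 * sel_net[n] / intra_counts[n]
                if intra_counts[n]
                else 0.0,
            }
        )
    rows.append(
        {
            "network": "Sum",
            "n_intra_connections": int(intra_counts.sum()),
            "n_selected": total_sel,
            "A_pct": 100.0 if total_sel else 0.0,
            "B_pct": 100.0 * total_sel / intra_counts.sum()
            if intra_counts.sum()
            else 0.0,
        }
    )
    return pd.DataFrame(rows)


def _network_groups(
    classification: pd.DataFrame,
    network_names,
    min_connections: int = 2,
) -> dict:
    """Connection indices of each network's intra-network connections.

    Networks with fewer than ``min_connections`` usable connections are
    dropped with a warning (their statistics would be undefined).
    """
    groups = {}
    net_col = classification["network"].to_numpy()
    intra = classification["intra"].to_numpy()
    for n in network_names:
        idx = np.flatnonzero(intra & (net_col == n))
        if idx.size >= min_connections:
            groups[n] = idx
        else:
            warnings.warn(
                f"network {n!r} has {idx.size} intra-network connection(s); "
                "excluded from group statistics",
                stacklevel=3,
            )
    return groups


def network_shared_anova(
    avg_csa: np.ndarray,
    classification: pd.DataFrame,
    network_names,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Genes whose coupling contribution does not differ across networks.

    One-way ANOVA per gene over the per-network groups of intra-network
    connections; a gene is *shared* iff P >= ``alpha``.  Returns
    ``(shared_mask, pvalues)`` over genes.
    """
    avg_csa = np.asarray(avg_csa, dtype=float)
    groups = _network_groups(classification, network_names)
    if len(groups) < 2:
        raise ValueError("fewer than 2 networks with usable connections")
    samples = [avg_csa[:, idx] for idx in groups.values()]
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.f_oneway(*samples, axis=1)
    # a gene constant everywhere has 0/0 F; no difference -> shared (P = 1)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return pvals >= alpha, pvals


def per_network_tensor_candidates(
    tensor: CouplingTensor,
    classification: pd.DataFrame,
    network_names,
    rank: int = 10,
    seed: int = 0,
    **cp_kwargs,
) -> tuple[dict, set]:
    """Criterion-1 candidates: per-network CP decomposition + mean+SD rule.

    The coupling tensor is restricted to each network's intra-network
    connections and decomposed (individual mode nonnegative); genes whose
    absolute leading-component weights exceed mean+SD of all genes form that
    network's candidate set.  Returns per-network sets of gene indices and
    their union.
    """
    groups = _network_groups(classification, network_names, min_connections=1)
    per_network: dict = {}
    seeds = np.random.SeedSequence(seed).generate_state(len(groups))
    for (name, idx), sub_seed in zip(groups.items(), seeds):
        sub = tensor.values[:, idx, :]
        if np.all(sub == 0):
            warnings.warn(f"all-zero sub-tensor for network {name!r}", stacklevel=2)
            per_network[name] = set()
            continue
        r_eff = min(rank, *sub.shape)
        if r_eff < rank:
            warnings.warn(
                f"network {name!r}: rank reduced from {rank} to {r_eff}",
                stacklevel=2,
            )
        result = cp_decompose_seminonneg(
            sub, rank=r_eff, seed=int(sub_seed) % (2**31), **cp_kwargs
        )
        leading, _ = select_leading_component(result)
        mask = weight_threshold_select(leading.gene_weights)
        per_network[name] = set(np.flatnonzero(mask))
    union = set().union(*per_network.values()) if per_network else set()
    return per_network, union


@dataclass
class SIStatistic:
    """Specificity of one gene to one network, with its permutation p."""

    gene: object
    network: str
    si_value: float
    permutation_p: float
    significant: bool


def specificity_index(
    gene_values: np.ndarray,
    classification: pd.DataFrame,
    target_network: str,
    network_names,
    n_perm: int = 1000,
    seed: int = 0,
    gene=None,
) -> SIStatistic:
    """Target-vs-rest specificity with a size-preserving permutation null.

    SI is the mean population-averaged C_sa over the target network's
    intra-network connections minus the pooled mean over all other networks'
    intra-network connections.  The null reassigns network labels to
    intra-network connections at random (group sizes preserved); the gene is
    significant for the network only if the observed SI strictly exceeds all
    ``n_perm`` permuted values.
    """
    if n_perm < 1000:
        warnings.warn(
            "fewer than 1000 permutations: P < 0.001 unattainable", stacklevel=2
        )
    gene_values = np.asarray(gene_values, dtype=float)
    groups = _network_groups(classification, network_names, min_connections=1)
    if target_network not in groups:
        raise ValueError(f"no intra-network connections for {target_network!r}")
    intra_idx = np.concatenate(list(groups.values()))
    vals = gene_values[intra_idx]
    n_target = groups[target_network].size
    is_target = np.zeros(vals.size, dtype=bool)
    offset = 0
    for name, idx in groups.items():
        if name == target_network:
            is_target[offset : offset + idx.size] = True
        offset += idx.size

    def _si(v):
        return v[is_target].mean() - v[~is_target].mean()

    observed = _si(vals)
    rng = np.random.default_rng(seed)
    n_exceed = 0
    for _ in range(n_perm):
        if _si(rng.permutation(vals)) >= observed:
            n_exceed += 1
    p = (n_exceed + 1) / (n_perm + 1)
    return SIStatistic(
        gene=gene,
        network=target_network,
        si_value=float(observed),
        permutation_p=float(p),
        significant=n_exceed == 0,
    )


@dataclass
class PosthocResult:
    """First-vs-second network comparison for one gene."""

    first_network: str
    second_network: str
    first_mean: float
    second_mean: float
    fold_ratio: float
    t_p: float
    anova_p: float
    passes: bool


def posthoc_specificity(
    gene_values: np.ndarray,
    classification: pd.DataFrame,
    network_names,
    anova_alpha: float | None = None,
    ratio_required: float = 2.0,
    t_alpha: float = 0.05,
) -> PosthocResult:
    """Criteria 3+4: ANOVA gate, twice-greater ratio, and Welch t-test.

    Networks are ranked by the gene's connection-averaged mean C_sa (absolute
    values, with a warning, when means carry mixed signs); the gene passes
    iff the across-network ANOVA rejects at ``anova_alpha`` (when given),
    the first mean is at least ``ratio_required`` times the second, and a
    Welch two-sample t-test on the two networks' per-connection values gives
    P < ``t_alpha``.
    """
    gene_values = np.asarray(gene_values, dtype=float)
    groups = _network_groups(classification, network_names, min_connections=1)
    if len(groups) < 2:
        raise ValueError("need at least 2 networks with connections")
    means = {n: gene_values[idx].mean() for n, idx in groups.items()}
    vals = np.array(list(means.values()))
    if np.any(vals < 0) and np.any(vals > 0):
        warnings.warn(
            "network means carry mixed signs; ranking by absolute value",
            stacklevel=2,
        )
    rank_key = np.abs(vals) if np.any(vals < 0) else vals
    order = np.argsort(rank_key)[::-1]
    names = list(means)
    first, second = names[order[0]], names[order[1]]
    m1, m2 = abs(means[first]), abs(means[second])
    ratio = m1 / m2 if m2 > 0 else np.inf

    anova_p = np.nan
    anova_ok = True
    if anova_alpha is not None:
        usable = [gene_values[idx] for idx in groups.values() if idx.size >= 2]
        if len(usable) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                anova_p = float(stats.f_oneway(*usable).pvalue)
            if np.isnan(anova_p):
                anova_p = 1.0
            anova_ok = anova_p < anova_alpha
        else:
            anova_ok = False

    if groups[first].size < 2 or groups[second].size < 2:
        warnings.warn(
            "a top network has a single connection; t-test skipped, "
            "criterion fails",
            stacklevel=2,
        )
        t_p = np.nan
        t_ok = False
    else:
        t_p = float(
            stats.ttest_ind(
                gene_values[groups[first]],
                gene_values[groups[second]],
                equal_var=False,
            ).pvalue
        )
        t_ok = t_p < t_alpha
    passes = anova_ok and ratio >= ratio_required and t_ok
    return PosthocResult(
        first_network=first,
        second_network=second,
        first_mean=float(means[first]),
        second_mean=float(means[second]),
        fold_ratio=float(ratio),
        t_p=t_p,
        anova_p=anova_p,
        passes=passes,
    )


@dataclass
class NetworkSpecificityReport:
    """Per-gene audit trail and per-criterion survivor counts."""

    gene_table: pd.DataFrame     # one row per (gene, candidate network)
    survivor_counts: pd.DataFrame  # per-network counts after each criterion
    labels: dict                 # gene id -> final network label


def network_specific_pipeline(
    tensor: CouplingTensor,
    classification: pd.DataFrame,
    network_names,
    rank: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
    **cp_kwargs,
) -> NetworkSpecificityReport:
    """Apply the four network-specificity criteria in order.

    Criterion 1 builds per-network candidate sets via tensor decomposition;
    criterion 2 keeps candidates whose SI beats all permutations for their
    network; criteria 3+4 apply the ANOVA gate (Bonferroni level
    0.05 / number-of-criterion-2-survivors, computed dynamically) and the
    twice-greater + t-test comparison.  A gene receives its final label only
    if the post-hoc first-ranked network matches the SI-significant network.
    """
    avg = tensor.population_average
    per_network, _union = per_network_tensor_candidates(
        tensor, classification, network_names, rank=rank, seed=seed, **cp_kwargs
    )
    ss = np.random.SeedSequence(seed + 1)
    rows = []
    si_pass: list[tuple[int, str, SIStatistic]] = []
    for name in network_names:
        candidates = sorted(per_network.get(name, set()))
        seeds = ss.spawn(len(candidates)) if candidates else []
        for a, child in zip(candidates, seeds):
            si = specificity_index(
                avg[a],
                classification,
                name,
                network_names,
                n_perm=n_perm,
                seed=int(child.generate_state(1)[0]) % (2**31),
                gene=tensor.gene_ids[a],
            )
            rows.append(
                {
                    "gene": tensor.gene_ids[a],
                    "candidate_network": name,
                    "si_value": si.si_value,
                    "si_p": si.permutation_p,
                    "si_significant": si.significant,
                }
            )
            if si.significant:
                si_pass.append((a, name, si))

    n_candidates = len({a for a, _, _ in si_pass})
    anova_alpha = 0.05 / n_candidates if n_candidates else None
    labels: dict = {}
    posthoc_rows = []
    final_by_network = {n: 0 for n in network_names}
    for a, name, si in si_pass:
        ph = posthoc_specificity(
            avg[a], classification, network_names, anova_alpha=anova_alpha
        )
        labeled = ph.passes and ph.first_network == name
        posthoc_rows.append(
            {
                "gene": tensor.gene_ids[a],
                "candidate_network": name,
                "anova_p": ph.anova_p,
                "first_network": ph.first_network,
                "second_network": ph.second_network,
                "fold_ratio": ph.fold_ratio,
                "t_p": ph.t_p,
                "label": name if labeled else "",
            }
        )
        if labeled:
            labels[tensor.gene_ids[a]] = name
            final_by_network[name] += 1

    gene_table = pd.DataFrame(rows)
    if posthoc_rows:
        gene_table = gene_table.merge(
            pd.DataFrame(posthoc_rows), on=["gene", "candidate_network"], how="left"
        )
    counts = pd.DataFrame(
        {
            "network": list(network_names),
            "criterion_1": [len(per_network.get(n, set())) for n in network_names],
            "criteria_1_2": [
                sum(1 for _, name, _ in si_pass if name == n) for n in network_names
            ],
            "criteria_1_2_3_4": [final_by_network[n] for n in network_names],
        }
    )
    return NetworkSpecificityReport(
        gene_table=gene_table, survivor_counts=counts, labels=labels
    )
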