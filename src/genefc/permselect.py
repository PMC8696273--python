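"""Permutation inference for genes and mean+SD selection of connections.

Two independent routes identify the structure of interest and are then
intersected:

* **genes** — the tensor-decomposition route (see :mod:`genefc.cpdecomp`)
  and a permutation test on the population- and connection-averaged C_sa of
  each gene: entries of the population-averaged gene x connection matrix
  are jointly shuffled (flatten-permute-reshape, destroying both gene and
  connection structure), the per-gene mean is recomputed per permutation,
  and a gene is significant only when its observed mean exceeds *all* null
  means (P < 1/n_perm, one-sided);
* **connections** — per-connection population-averaged coupling CEC_s
  thresholded at |CEC| > mean+SD, intersected with the mean+SD selection on
  the leading CP component's connection weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class PermutationResult:
    """Per-gene permutation-null summary for the mean-contribution test."""

    observed: np.ndarray          # per-gene observed mean C_sa
    null_max: np.ndarray          # per-gene max over permutation means
    n_exceeding: np.ndarray       # per-gene count of null means >= observed
    pvalues: np.ndarray           # (n_exceeding + 1) / (n_perm + 1)
    significant: np.ndarray       # observed > all null means
    n_permutations: int

    @property
    def significant_indices(self) -> np.ndarray:
        return np.flatnonzero(self.significant)


def permutation_null_gene_means(
    avg_csa: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "full",
) -> PermutationResult:
    """Permutation null for each gene's connection-averaged mean C_sa.

    ``mode="full"`` (default) shuffles all matrix entries jointly;
    ``mode="within_connection"`` permutes each connection's column
    independently, preserving per-connection marginals.  A gene is declared
    significant when its observed row mean is strictly greater than every
    permutation-derived mean for that row; the attached empirical p-value is
    ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    avg_csa = np.asarray(avg_csa, dtype=float)
    if avg_csa.ndim != 2:
        raise ValueError("expected a gene x connection matrix")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 1000:
        warnings.warn(
            "fewer than 1000 permutations: the P < 0.001 criterion of the "
            "reference analysis is unattainable",
            stacklevel=2,
        )
    if mode not in ("full", "within_connection"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    rng = np.random.default_rng(seed)
    G, S = avg_csa.shape
    observed = avg_csa.mean(axis=1)
    null_max = np.full(G, -np.inf)
    n_exceeding = np.zeros(G, dtype=int)
    flat = avg_csa.ravel()
    for _ in range(n_perm):
        if mode == "full":
            null = rng.permutation(flat).reshape(G, S).mean(axis=1)
        else:
            null = rng.permuted(avg_csa, axis=0).mean(axis=1)
        null_max = np.maximum(null_max, null)
        n_exceeding += null >= observed
    pvalues = (n_exceeding + 1) / (n_perm + 1)
    return PermutationResult(
        observed=observed,
        null_max=null_max,
        n_exceeding=n_exceeding,
        pvalues=pvalues,
        significant=observed > null_max,
        n_permutations=n_perm,
    )


def reliable_gene_intersection(tensor_genes, permutation_genes) -> set:
    """Genes identified by both the tensor and the permutation route."""
    return set(tensor_genes) & set(permutation_genes)


def cec_connection_select(cec: np.ndarray, use_abs: bool = True) -> np.ndarray:
    """Connections with |CEC_s| strictly above mean+SD of all connections.

    ``use_abs=False`` thresholds the signed values instead.  Sample SD
    (ddof=1); constant input yields an empty selection with a warning.
    """
    cec = np.asarray(cec, dtype=float)
    if cec.size < 2:
        raise ValueError("need at least 2 connections")
    scores = np.abs(cec) if use_abs else cec
    sd = scores.std(ddof=1)
    if sd == 0:
        warnings.warn("constant CEC vector: empty selection", stacklevel=2)
        return np.zeros(cec.size, dtype=bool)
    return scores > scores.mean() + sd


@dataclass
class ConnectionSelection:
    """Two-route connection selection and its intersection."""

    cec_route: set
    tensor_route: set
    final: set
    containment: float  # fraction of the tensor route inside the CEC route

    def __post_init__(self) -> None:
        if not self.final <= self.cec_route or not self.final <= self.tensor_route:
            raise ValueError("final selection must be contained in both routes")


def connection_selection_combine(cec_route, tensor_route) -> ConnectionSelection:
    """Intersect the CEC-threshold and tensor-weight connection selections."""
    cec_route = set(cec_route)
    tensor_route = set(tensor_route)
    final = cec_route & tensor_route
    containment = (
        len(final) / len(tensor_route) if tensor_route else float("nan")
    )
    return ConnectionSelection(
        cec_route=cec_route,
        tensor_route=tensor_route,
        final=final,
        containment=containment,
    )
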