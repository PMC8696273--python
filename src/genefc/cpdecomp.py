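"""Semi-nonnegative CP decomposition of the coupling tensor.

The gene x connection x subject coupling tensor is factorized with a
canonical polyadic (CP) model

    X[g, s, h]  ~  sum_r  scale_r * a_r[g] * b_r[s] * c_r[h]

where the subject (individual) factors ``c_r`` are constrained nonnegative —
subjects act as nonnegative mixture weights over coupling patterns — while
gene and connection factors may carry sign.  Fitting is alternating least
squares: free modes are updated by exact linear least squares, the
constrained mode by exact nonnegative least squares (row-wise NNLS), so the
reconstruction error is non-increasing across sweeps.  Multiple random
restarts guard against poor local optima; factors are unit-normalized with
the magnitude absorbed into a nonnegative component scale (the component
"output score"), and components are returned ordered by scale.

Utilities for the group-level workflow live here too: deterministic
site-stratified splitting of subjects into four groups, mean+SD weight
thresholding, cross-group consistency metrics, and the 100%-repeated-rate
intersection of per-group gene selections.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import nnls


@dataclass
class CPComponent:
    """One CP component: scale plus unit-norm weight vectors per mode."""

    scale: float
    gene_weights: np.ndarray
    connection_weights: np.ndarray
    individual_weights: np.ndarray

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("component scale must be nonnegative")
        if np.any(self.individual_weights < -1e-12):
            raise ValueError("individual weights must be nonnegative")


@dataclass
class DecompositionResult:
    """CP fit: components ordered by scale (descending) plus diagnostics."""

    components: list
    rank: int
    converged: bool
    n_iterations: int
    final_fit: float                 # relative reconstruction error
    fit_history: list = field(default_factory=list)

    @property
    def scales(self) -> np.ndarray:
        return np.array([c.scale for c in self.components])


def _factor_inner(X: np.ndarray, A: np.ndarray, B: np.ndarray, mode: int) -> np.ndarray:
    """Matricized tensor times Khatri-Rao product for the given mode."""
    if mode == 0:
        return np.einsum("gsh,sr,hr->gr", X, A, B, optimize=True)
    if mode == 1:
        return np.einsum("gsh,gr,hr->sr", X, A, B, optimize=True)
    return np.einsum("gsh,gr,sr->hr", X, A, B, optimize=True)


def _solve_ls(gram: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """rhs @ gram^{-1} with a pseudo-inverse fallback for rank deficiency."""
    try:
        return np.linalg.solve(gram.T, rhs.T).T
    except np.linalg.LinAlgError:
        return rhs @ np.linalg.pinv(gram)


def _als_run(
    X: np.ndarray,
    rank: int,
    constrained: tuple,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[list, float, bool, int, list]:
    G, S, H = X.shape
    dims = (G, S, H)
    factors = []
    for mode, d in enumerate(dims):
        f = rng.standard_normal((d, rank))
        if mode in constrained:
            f = np.abs(f)
        factors.append(f)
    norm_x = float(np.linalg.norm(X))
    history: list[float] = []
    prev_err = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            M = _factor_inner(X, *others, mode=mode)
            gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
            F = _solve_ls(gram, M)
            if mode in constrained and np.any(F < 0):
                # exact NNLS only where the unconstrained solution violates
                kr = (
                    others[0][:, None, :] * others[1][None, :, :]
                ).reshape(-1, rank)
                unfold = np.moveaxis(X, mode, 0).reshape(dims[mode], -1)
                for row in np.flatnonzero((F < 0).any(axis=1)):
                    F[row], _ = nnls(kr, unfold[row])
            factors[mode] = F
        # relative reconstruction error from cached inner products
        last = factors[2]
        M = _factor_inner(X, factors[0], factors[1], mode=2)
        inner = float(np.sum(M * last))
        norm_hat_sq = float(
            np.sum(
                (factors[0].T @ factors[0])
                * (factors[1].T @ factors[1])
                * (last.T @ last)
            )
        )
        err = np.sqrt(max(norm_x**2 + norm_hat_sq - 2 * inner, 0.0)) / norm_x
        history.append(err)
        if abs(prev_err - err) < tol:
            converged = True
            break
        prev_err = err
    return factors, history[-1], converged, it, history


def cp_decompose_seminonneg(
    tensor: np.ndarray,
    rank: int = 10,
    constraint_modes: tuple = (2,),
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 5,
) -> DecompositionResult:
    """Fit the semi-nonnegative CP model to a (gene, connection, subject)
    array.

    ``constraint_modes`` selects which modes are nonnegativity-constrained;
    the default constrains only mode 2, the individual/subject mode.  The
    best of ``n_restarts`` random initializations (by final relative error)
    is returned; everything is deterministic given ``seed``.
    """
    X = np.asarray(getattr(tensor, "values", tensor), dtype=float)
    if X.ndim != 3:
        raise ValueError("expected a 3-way array")
    if not np.isfinite(X).all():
        raise ValueError("tensor contains NaN or infinite entries")
    if np.all(X == 0):
        raise ValueError("all-zero tensor has no CP decomposition")
    if rank < 1 or any(rank > d for d in X.shape):
        raise ValueError(f"rank must be in [1, min{X.shape}]")
    constrained = tuple(constraint_modes)

    best = None
    for child in np.random.SeedSequence(seed).spawn(n_restarts):
        rng = np.random.default_rng(child)
        run = _als_run(X, rank, constrained, rng, tol, max_iter)
        if best is None or run[1] < best[1]:
            best = run
    factors, final_err, converged, n_iter, history = best
    if not converged:
        warnings.warn(
            f"CP-ALS did not converge within {max_iter} iterations "
            f"(final relative error {final_err:.3g})",
            stacklevel=2,
        )

    # normalize columns, absorb magnitude into component scales
    norms = [np.linalg.norm(f, axis=0) for f in factors]
    scales = norms[0] * norms[1] * norms[2]
    unit = []
    for f, nrm in zip(factors, norms):
        safe = np.where(nrm > 0, nrm, 1.0)
        unit.append(f / safe)
    components = []
    for r in np.argsort(scales)[::-1]:
        a, b, c = unit[0][:, r].copy(), unit[1][:, r].copy(), unit[2][:, r].copy()
        # sign indeterminacy between the two free modes: anchor the gene
        # vector's largest-magnitude entry positive
        if a[np.argmax(np.abs(a))] < 0:
            a, b = -a, -b
        c = np.clip(c, 0.0, None)
        if scales[r] == 0:
            warnings.warn("zero-scale (degenerate) component", stacklevel=2)
        components.append(
            CPComponent(
                scale=float(scales[r]),
                gene_weights=a,
                connection_weights=b,
                individual_weights=c,
            )
        )
    return DecompositionResult(
        components=components,
        rank=rank,
        converged=converged,
        n_iterations=n_iter,
        final_fit=final_err,
        fit_history=history,
    )


def select_leading_component(result: DecompositionResult) -> tuple[CPComponent, float]:
    """Component with the largest scale and its dominance ratio.

    The ratio (leading scale / runner-up scale) lets callers check that the
    leading component truly dominates; ties produce a warning and the first
    component in stable order is returned.
    """
    if not result.components:
        raise ValueError("empty decomposition result")
    leading = result.components[0]
    if len(result.components) == 1:
        return leading, np.inf
    runner = result.components[1].scale
    if np.isclose(leading.scale, runner, rtol=1e-9, atol=1e-12):
        warnings.warn("leading-component tie; keeping stable order", stacklevel=2)
    ratio = leading.scale / runner if runner > 0 else np.inf
    return leading, ratio


def weight_threshold_select(weights: np.ndarray) -> np.ndarray:
    """Boolean mask of items with |weight| strictly above mean+SD.

    Mean and SD (sample SD, ddof=1) are taken over the absolute weights of
    all items, so the selection is invariant under positive rescaling of the
    weight vector.
    """
    w = np.abs(np.asarray(weights, dtype=float))
    if w.size < 2:
        raise ValueError("need at least 2 items")
    sd = w.std(ddof=1)
    if sd == 0:
        warnings.warn("constant weights: empty selection", stacklevel=2)
        return np.zeros(w.size, dtype=bool)
    return w > w.mean() + sd


def split_groups(subject_ids, site_labels=None, seed: int = 0) -> list:
    """Split subjects into four groups, randomly halving within each site.

    With two sites each site is halved (four groups total); with a single
    site (or ``site_labels=None``) subjects are shuffled and split into four
    near-equal groups.  Deterministic given ``seed``.
    """
    subject_ids = list(subject_ids)
    rng = np.random.default_rng(seed)
    if site_labels is None:
        site_labels = ["site0"] * len(subject_ids)
    site_labels = list(site_labels)
    if len(site_labels) != len(subject_ids):
        raise ValueError("site label per subject required")
    sites = sorted(set(site_labels))
    groups: list[list] = []
    if len(sites) == 1:
        order = rng.permutation(len(subject_ids))
        for part in np.array_split(order, 4):
            groups.append([subject_ids[k] for k in part])
    elif len(sites) == 2:
        for site in sites:
            members = [k for k, lab in enumerate(site_labels) if lab == site]
            order = rng.permutation(len(members))
            half = len(members) // 2
            for part in (order[:half], order[half:]):
                groups.append([subject_ids[members[k]] for k in part])
    else:
        raise ValueError("expected one or two site labels")
    if any(len(g) < 2 for g in groups):
        raise ValueError("a split group has fewer than 2 subjects")
    return groups


def cross_group_consistency(components: list) -> tuple[float, float]:
    """Agreement of leading components fit independently in four groups.

    Returns ``(mismatch_rate, mean_correspondence)``: correspondence is the
    mean over the 6 group pairs of the absolute Pearson correlation between
    gene-weight vectors (absolute value handles CP sign indeterminacy);
    mismatch rate is the Jaccard distance ``1 - |intersection| / |union|``
    of the four per-group mean+SD gene selections.
    """
    if len(components) != 4:
        raise ValueError("expected four group components")
    vecs = [np.asarray(c.gene_weights, dtype=float) for c in components]
    n = vecs[0].size
    if any(v.size != n for v in vecs):
        raise ValueError("gene-weight dimension mismatch across groups")
    corrs = [
        abs(stats.pearsonr(u, v).statistic)
        for u, v in itertools.combinations(vecs, 2)
    ]
    selections = [set(np.flatnonzero(weight_threshold_select(v))) for v in vecs]
    union = set.union(*selections)
    inter = set.intersection(*selections)
    mismatch = 1.0 - (len(inter) / len(union)) if union else 0.0
    return mismatch, float(np.mean(corrs))


def repeated_gene_selection(selections: list) -> set:
    """Genes selected in every group (100% repeated rate): set intersection."""
    sets = [set(s) for s in selections]
    if not sets:
        return set()
    return set.intersection(*sets)
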