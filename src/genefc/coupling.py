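"""Core coupling statistics between regional co-expression and connectivity.

Three statistics define the whole analysis:

* **CGE** (correlated gene expression) of a region pair (i, j): the mean over
  genes of the product of normalized expression values,
  ``CGE_ij = sum_a(E_ia * E_ja) / N``.  Under the default normalization this
  equals the Pearson correlation of the two regions' expression profiles.
* **global CEC** (connectivity-expression coupling) of a subject: the mean
  over connections of ``FC_s * CGE_s`` with both vectors z-scored across
  connections — the Pearson correlation between a subject's connectivity
  profile and the co-expression profile.
* **C_sa**, the contribution of gene ``a`` to the coupling at connection
  ``s``: ``C_sa = (FC_s * CGE_s) * (E_ia * E_ja)``, giving a
  gene x connection x subject coupling tensor.

Normalization conventions (documented per function): population standard
deviation (divisor ``n``) is used wherever a mean of products must equal a
Pearson correlation; sample SD (``n-1``) is used for mean+SD selection
thresholds elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import connection_pairs, n_connections


def _zscore(x: np.ndarray, axis: int) -> np.ndarray:
    """z-score with population SD (ddof=0)."""
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=0, keepdims=True)
    return (x - mu) / sd


@dataclass
class ExpressionMatrix:
    """Region x gene normalized expression (z-score units).

    ``values[i, a]`` is E_ia.  Produced by :func:`normalize_expression`.
    """

    values: np.ndarray
    region_ids: list
    gene_ids: list
    mode: str = "pearson"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression must be a 2-D region x gene matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("expression contains non-finite values")
        if self.values.shape != (len(self.region_ids), len(self.gene_ids)):
            raise ValueError("expression shape inconsistent with identifiers")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.region_ids, columns=self.gene_ids).to_csv(
            path, sep="\t", index_label="region_id"
        )

    @classmethod
    def from_tsv(cls, path, mode: str = "pearson") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), list(df.index), list(df.columns), mode=mode)


def normalize_expression(raw, region_ids=None, gene_ids=None, mode: str = "pearson") -> ExpressionMatrix:
    """Normalize a raw region x gene matrix into z-score units.

    Each gene column is z-scored across regions using the population SD.  In
    the default ``mode="pearson"`` each region row is then additionally
    standardized across genes (mean 0, unit population SD), which makes the
    mean-of-products CGE exactly the Pearson correlation between two regions'
    expression profiles, as the coupling framework asserts; the row second
    moment ``mean_a(E_ia^2)`` is 1.  ``mode="literal"`` skips the row step and
    keeps exact per-gene z-scores (CGE is then only approximately a Pearson
    correlation).

    Raises
    ------
    ValueError
        If any gene has constant expression across regions (named in the
        message), or fewer than 3 regions are supplied.
    """
    if isinstance(raw, pd.DataFrame):
        region_ids = list(raw.index) if region_ids is None else region_ids
        gene_ids = list(raw.columns) if gene_ids is None else gene_ids
        raw = raw.to_numpy(float)
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 regions")
    if region_ids is None:
        region_ids = list(range(raw.shape[0]))
    if gene_ids is None:
        gene_ids = [f"g{a}" for a in range(raw.shape[1])]
    if mode not in ("pearson", "literal"):
        raise ValueError(f"unknown normalization mode {mode!r}")

    sd = raw.std(axis=0, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [str(gene_ids[a]) for a in bad[:5]]
        raise ValueError(f"constant expression for gene(s): {', '.join(names)}")
    vals = _zscore(raw, axis=0)
    if mode == "pearson":
        vals = _zscore(vals, axis=1)
    return ExpressionMatrix(vals, list(region_ids), list(gene_ids), mode=mode)


@dataclass
class ConnectivitySet:
    """Subject x connection normalized functional connectivity.

    Rows are per-subject connection vectors in canonical upper-triangle
    order; after :func:`normalize_connectivity` each row has mean 0 and unit
    population variance across connections.
    """

    values: np.ndarray
    subject_ids: list
    n_regions: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("connectivity must be subject x connection")
        if self.values.shape[1] != n_connections(self.n_regions):
            raise ValueError(
                f"{self.values.shape[1]} connections inconsistent with "
                f"{self.n_regions} regions"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_conn(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        iu, ju = connection_pairs(self.n_regions)
        cols = [f"{i}_{j}" for i, j in zip(iu, ju)]
        pd.DataFrame(self.values, index=self.subject_ids, columns=cols).to_csv(
            path, sep="\t", index_label="subject_id"
        )

    @classmethod
    def from_tsv(cls, path, n_regions: int) -> "ConnectivitySet":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), list(df.index), n_regions)


def normalize_connectivity(
    raw: np.ndarray,
    n_regions: int,
    subject_ids=None,
    fisher: bool = True,
) -> ConnectivitySet:
    """Per-subject normalization of raw connectivity vectors.

    With ``fisher=True`` (for raw Pearson-correlation FC in (-1, 1)) each
    value is Fisher r-to-z transformed (``arctanh``) first; set
    ``fisher=False`` for connectivity already on an unbounded scale.  Each
    subject's vector is then z-scored across its connections with the
    population SD, so a subsequent mean of products with a z-scored CGE
    vector is a Pearson correlation.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if raw.shape[1] < 3:
        raise ValueError("need at least 3 connections per subject")
    if fisher:
        if np.any(np.abs(raw) >= 1):
            raise ValueError("|r| >= 1 entries: Fisher transform diverges")
        raw = np.arctanh(raw)
    vals = _zscore(raw, axis=1)
    if subject_ids is None:
        subject_ids = [f"sub{s:04d}" for s in range(raw.shape[0])]
    return ConnectivitySet(vals, list(subject_ids), n_regions)


# ---------------------------------------------------------------------------
# CGE
# ---------------------------------------------------------------------------

def compute_cge(expr: ExpressionMatrix, i: int, j: int) -> float:
    """CGE of region pair (i, j): mean over genes of E_ia * E_ja.

    Under the default ("pearson") normalization this equals the Pearson
    correlation of the two regions' expression profiles across genes.
    """
    if i == j:
        raise ValueError("self-connection CGE is undefined (i == j)")
    return float(np.mean(expr.values[i] * expr.values[j]))


@dataclass
class CgeVector:
    """Per-connection CGE values, aligned to the canonical connection order.

    ``raw`` holds CGE_ij as defined (in [-1, 1] under the default
    normalization); ``zscored`` is raw z-scored across connections with the
    population SD — the "normalized correlated gene expression" entering the
    CEC and C_sa computations.
    """

    raw: np.ndarray
    n_regions: int
    zscored: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (n_connections(self.n_regions),):
            raise ValueError("CGE vector length inconsistent with region count")
        self.zscored = _zscore(self.raw[None, :], axis=1)[0]


def compute_cge_vector(expr: ExpressionMatrix) -> CgeVector:
    """CGE for all region pairs at once (gram matrix over genes / N)."""
    gram = expr.values @ expr.values.T / expr.n_genes
    iu, ju = connection_pairs(expr.n_regions)
    return CgeVector(gram[iu, ju], expr.n_regions)


# ---------------------------------------------------------------------------
# CEC and the coupling tensor
# ---------------------------------------------------------------------------

def compute_global_cec(fc: np.ndarray, cge: np.ndarray) -> float:
    """Global coupling of one subject: mean over connections of FC_s * CGE_s.

    Both inputs must already be z-scored across connections (population SD),
    making the result the Pearson correlation between the subject's
    connectivity and the co-expression profile.
    """
    fc = np.asarray(fc, dtype=float)
    cge = np.asarray(cge, dtype=float)
    if fc.shape != cge.shape:
        raise ValueError(f"length mismatch: {fc.shape} vs {cge.shape}")
    return float(np.mean(fc * cge))


def compute_csa(fc_s: float, cge_s: float, e_ia: float, e_ja: float) -> float:
    """Contribution of one gene to the coupling at one connection.

    ``(FC_s * CGE_s) * (E_ia * E_ja)`` with FC_s and CGE_s the normalized
    per-connection values and E the normalized expression.
    """
    return (fc_s * cge_s) * (e_ia * e_ja)


@dataclass
class CouplingTensor:
    """Gene x connection x subject coupling contributions C_sa.

    ``values[a, s, h]`` is gene ``a``'s contribution at connection ``s`` for
    subject ``h``.  ``population_average`` (gene x connection) and
    ``gene_means`` (per gene, averaged over connections then subjects) are
    plain arithmetic means; averaging over subjects and connections commutes.
    """

    values: np.ndarray
    gene_ids: list
    subject_ids: list
    n_regions: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("coupling tensor must be 3-way")
        if self.values.shape[1] != n_connections(self.n_regions):
            raise ValueError("connection axis inconsistent with region count")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conn(self) -> int:
        return self.values.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[2]

    @property
    def population_average(self) -> np.ndarray:
        """Gene x connection matrix averaged over subjects."""
        return self.values.mean(axis=2)

    @property
    def gene_means(self) -> np.ndarray:
        """Population- and connection-averaged contribution per gene."""
        return self.values.mean(axis=(1, 2))

    def restrict_connections(self, mask: np.ndarray) -> np.ndarray:
        """Sub-tensor on a boolean connection mask (view-copy)."""
        return self.values[:, np.asarray(mask, bool), :]


def build_coupling_tensor(
    expr: ExpressionMatrix,
    conn: ConnectivitySet,
    gene_subset=None,
) -> CouplingTensor:
    """Dense C_sa tensor for all (gene, connection, subject) triples.

    The connection-level coupling term ``FC_s * CGE_s^norm`` is shared across
    genes; the gene factor is the co-expression product ``E_ia * E_ja``.
    ``gene_subset`` (sequence of gene identifiers) restricts the gene axis —
    the reference analysis builds the tensor on the screened gene pool only.
    """
    if expr.n_regions != conn.n_regions:
        raise ValueError(
            f"region mismatch: expression has {expr.n_regions} regions, "
            f"connectivity implies {conn.n_regions}"
        )
    cge = compute_cge_vector(expr)
    if gene_subset is None:
        gene_idx = np.arange(expr.n_genes)
    else:
        pos = {g: a for a, g in enumerate(expr.gene_ids)}
        missing = [g for g in gene_subset if g not in pos]
        if missing:
            raise ValueError(f"unknown genes in subset: {missing[:5]}")
        gene_idx = np.array([pos[g] for g in gene_subset])
    iu, ju = connection_pairs(expr.n_regions)
    e = expr.values[:, gene_idx]
    products = e[iu] * e[ju]                      # connection x gene
    coupling = conn.values * cge.zscored[None, :]  # subject x connection
    tensor = products.T[:, :, None] * coupling.T[None, :, :]
    return CouplingTensor(
        tensor,
        [expr.gene_ids[a] for a in gene_idx],
        list(conn.subject_ids),
        expr.n_regions,
    )


def population_cec(conn: ConnectivitySet, cge: CgeVector) -> np.ndarray:
    """Population-averaged per-connection coupling CEC_s.

    Mean over subjects of ``FC_s^norm * CGE_s^norm`` at each connection.
    """
    return conn.values.mean(axis=0) * cge.zscored
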