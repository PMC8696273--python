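"""Brain parcellation bookkeeping: regions, networks, hemispheres, homologs.

A :class:`NetworkAtlas` maps each region of a parcellation to exactly one
functional network (seven canonical cortical resting-state networks plus a
subcortical network in the reference setting), a hemisphere, and a
contralateral homolog.  All connection-level statistics downstream are driven
by this table.

Connections (region pairs) are vectorized in row-major upper-triangle order:
pair ``(i, j)`` with ``i < j``, 0-based, ordered as produced by
``numpy.triu_indices``.  This single convention is used everywhere in the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical network names in the reference 90-region setting.
CANONICAL_NETWORKS = ("VN", "SMN", "DAN", "VAN", "LN", "FPN", "DMN", "subcortical")


def n_connections(n_regions: int) -> int:
    """Number of unordered region pairs, R*(R-1)/2."""
    return n_regions * (n_regions - 1) // 2


def connection_pairs(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (i, j) arrays for all connections, row-major upper triangle."""
    return np.triu_indices(n_regions, k=1)


def connection_id(i: int, j: int, n_regions: int) -> int:
    """Position of pair (i, j), i < j, in the canonical connection order."""
    if not 0 <= i < j < n_regions:
        raise ValueError(f"invalid pair ({i}, {j}) for {n_regions} regions")
    # row-major upper triangle offset
    return i * (2 * n_regions - i - 3) // 2 + j - 1


def square_to_vector(mat: np.ndarray) -> np.ndarray:
    """Vectorize a symmetric region x region matrix (upper triangle, i < j)."""
    r = mat.shape[0]
    iu, ju = connection_pairs(r)
    return np.asarray(mat)[iu, ju]


def vector_to_square(vec: np.ndarray, n_regions: int, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`square_to_vector`; returns a symmetric matrix."""
    mat = np.full((n_regions, n_regions), diag, dtype=float)
    iu, ju = connection_pairs(n_regions)
    mat[iu, ju] = vec
    mat[ju, iu] = vec
    return mat


@dataclass
class NetworkAtlas:
    """Region -> (network, hemisphere, homolog) assignment table.

    Parameters
    ----------
    table
        DataFrame with columns ``region_id`` (int, 0-based, contiguous),
        ``region_name``, ``network``, ``hemisphere`` (``L``/``R``/``midline``)
        and ``homolog_id`` (region_id of the contralateral homolog, or -1).
    """

    table: pd.DataFrame
    network_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        required = {"region_id", "region_name", "network", "hemisphere", "homolog_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        self.table = self.table.sort_values("region_id").reset_index(drop=True)
        ids = self.table["region_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("region_id must be 0-based and contiguous")
        if not self.network_names:
            # first-appearance order
            self.network_names = tuple(dict.fromkeys(self.table["network"]))
        self._validate_homologs()

    def _validate_homologs(self) -> None:
        hom = self.table["homolog_id"].to_numpy()
        net = self.table["network"].to_numpy()
        hemi = self.table["hemisphere"].to_numpy()
        for r, h in enumerate(hom):
            if h < 0:
                continue
            if hom[h] != r:
                raise ValueError(f"homolog pairing not mutual for region {r}")
            if h == r:
                raise ValueError(f"region {r} paired with itself")
            if net[h] != net[r]:
                raise ValueError(f"homolog pair ({r}, {h}) spans networks")
            if {hemi[r], hemi[h]} != {"L", "R"}:
                raise ValueError(f"homolog pair ({r}, {h}) not cross-hemisphere")

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> np.ndarray:
        """Per-region network label array."""
        return self.table["network"].to_numpy()

    @property
    def homolog_ids(self) -> np.ndarray:
        return self.table["homolog_id"].to_numpy()

    def homolog_pairs(self) -> list[tuple[int, int]]:
        """All homolog pairs (i, j) with i < j; each region in at most one."""
        hom = self.homolog_ids
        return [(r, int(h)) for r, h in enumerate(hom) if h >= 0 and r < h]

    def network_sizes(self) -> dict[str, int]:
        counts = self.table["network"].value_counts()
        return {name: int(counts.get(name, 0)) for name in self.network_names}

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "NetworkAtlas":
        return cls(pd.read_csv(path, sep="\t"))
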