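"""Haplotype collapse under two gap conventions, and the Max ID rate.

Two aligned sequences share a haplotype when they show zero point-mutation
mismatches at the positions where both are resolved.  Missing data and
IUPAC ambiguity codes are always wildcards; the alignment gap '-' is a
wildcard under ``gap_as_missing`` but an ordinary fifth symbol under
``gap_as_fifth_state`` (so gap-vs-base and gap-vs-missing then count as
mismatches).  Because wildcard identity is not transitive, haplotypes are
the connected components of the zero-mismatch link relation — the unique
maximal, order-independent merge.

The Max ID rate, 100 * unique haplotypes / species sampled, is the ceiling
on character-based species discrimination: it credits a species as
distinguishable on as little as a single base difference.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io_model import Dataset, InputError
from .distances import encode


class GapMode(str, enum.Enum):
    GAP_AS_MISSING = "gap_as_missing"
    GAP_AS_FIFTH_STATE = "gap_as_fifth_state"


@dataclass(frozen=True)
class HaplotypePartition:
    """Partition of a dataset's accessions into identical-sequence clusters."""

    gap_mode: GapMode
    clusters: tuple[tuple[str, ...], ...]

    @property
    def n_unique(self) -> int:
        return len(self.clusters)

    def cluster_of(self, accession: str) -> int:
        for k, members in enumerate(self.clusters):
            if accession in members:
                return k
        raise KeyError(accession)


def _conflicts(a: np.ndarray, b: np.ndarray, gap_mode: GapMode) -> bool:
    """Whether two encoded sequences show any point-mutation mismatch
    under the gap convention.

    Codes: 0..3 bases, 4 missing, 5 gap, 6 ambiguity.  Missing and
    ambiguity are wildcards in both modes.  Under gap_as_fifth_state the
    gap additionally mismatches both bases and missing data (an absent
    stretch cannot be the same character as an unread one), but not
    ambiguity codes, which stay fully wild.
    """
    if gap_mode is GapMode.GAP_AS_MISSING:
        both = (a < 4) & (b < 4)
        return bool(np.any((a != b) & both))
    resolved_a = (a < 4) | (a == 5)
    resolved_b = (b < 4) | (b == 5)
    base_conflict = (a != b) & resolved_a & resolved_b
    gap_vs_missing = ((a == 5) & (b == 4)) | ((a == 4) & (b == 5))
    return bool(np.any(base_conflict | gap_vs_missing))


def collapse_haplotypes(ds: Dataset, gap_mode: GapMode | str = GapMode.GAP_AS_MISSING
                        ) -> HaplotypePartition:
    """Collapse a dataset into haplotype clusters under the given gap mode.

    Clusters are connected components of the pairwise zero-mismatch
    relation; cluster order follows the first member's position in the
    dataset, members keep dataset order.
    """
    gap_mode = GapMode(gap_mode)
    labels = ds.accessions
    n = len(labels)
    codes = np.vstack([encode(ds.sequences[a]) for a in labels])
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if not _conflicts(codes[i], codes[j], gap_mode):
                rows.append(i)
                cols.append(j)
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, assignment = connected_components(graph, directed=False)
    clusters: dict[int, list[str]] = {}
    order: list[int] = []
    for idx, comp in enumerate(assignment):
        if comp not in clusters:
            clusters[comp] = []
            order.append(comp)
        clusters[comp].append(labels[idx])
    return HaplotypePartition(
        gap_mode=gap_mode,
        clusters=tuple(tuple(clusters[c]) for c in order),
    )


def max_id_rate(n_unique: int, n_species: int) -> float:
    """Maximum species-identification rate, 100 * n_unique / n_species (%)."""
    if n_species < 1:
        raise InputError("n_species must be >= 1")
    if n_unique < 1:
        raise InputError("n_unique must be >= 1")
    rate = 100.0 * n_unique / n_species
    if rate > 100.0:
        warnings.warn(
            "more unique sequences than species: Max ID rate exceeds 100% "
            "(expected only when multiple accessions per species are included)",
            stacklevel=2,
        )
    return round(rate, 2)


def count_variable_sites(ds: Dataset) -> int:
    """Alignment columns with >= 2 distinct unambiguous bases.

    Gaps, missing data and ambiguity codes are ignored when deciding
    whether a column varies.
    """
    codes = np.vstack([encode(ds.sequences[a]) for a in ds.accessions])
    n_var = 0
    for col in codes.T:
        bases = np.unique(col[col < 4])
        if bases.size >= 2:
            n_var += 1
    return n_var


def write_partition_tsv(part: HaplotypePartition, species_of, path) -> None:
    """Write the partition as TSV (cluster_id, accession, species)."""
    with open(path, "w") as fh:
        fh.write("cluster_id\taccession\tspecies\n")
        for k, members in enumerate(part.clusters):
            for acc in members:
                fh.write(f"{k}\t{acc}\t{species_of(acc)}\n")
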