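"""Kimura 2-parameter pairwise distances with pairwise deletion.

The K2P model corrects observed divergence for multiple hits while
distinguishing transitions (A<->G, C<->T) from transversions:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the proportions of transition- and transversion-differing
sites among the mutually resolved positions of a pair.  Columns where
either sequence carries a gap, a missing symbol or an IUPAC ambiguity code
are excluded per pair (pairwise deletion); ambiguity codes are treated as
missing, never partially matched.  Pairs whose overlap falls below a
minimum, or for which the logarithm's argument is non-positive
(saturation), carry an undefined flag instead of a value and are excluded
from all downstream summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_model import AlignmentError, Dataset

# residue codes: A,C,G,T -> 0..3; missing -> 4; gap -> 5; IUPAC ambiguity -> 6.
# transitions are A<->G and C<->T, i.e. exactly the code pairs with XOR == 2.
# For distances only code < 4 counts as resolved, so missing and ambiguity
# behave identically here; haplotype collapse needs the distinction.
_CODE = np.full(128, 4, dtype=np.uint8)
for _c, _v in zip("ACGT", range(4)):
    _CODE[ord(_c)] = _v
_CODE[ord("-")] = 5
for _c in "RYSWKMBDHV":
    _CODE[ord(_c)] = 6

DEFAULT_MIN_OVERLAP = 100


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as uint8 codes (see module header)."""
    return _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PairwiseCounts:
    """Site-pattern counts for one sequence pair after pairwise deletion."""

    n_sites: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self):
        if min(self.n_sites, self.n_transitions, self.n_transversions) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_transitions + self.n_transversions > self.n_sites:
            raise ValueError("differences exceed compared sites")


def count_site_patterns(seq_a: str, seq_b: str) -> PairwiseCounts:
    """Classify aligned columns of a pair into compared/transition/transversion.

    Columns where either residue is a gap, missing, or an ambiguity code are
    excluded from ``n_sites``.
    """
    if len(seq_a) != len(seq_b):
        raise AlignmentError(
            f"cannot compare sequences of lengths {len(seq_a)} and {len(seq_b)}"
        )
    a, b = encode(seq_a), encode(seq_b)
    valid = (a < 4) & (b < 4)
    diff = valid & (a != b)
    transitions = int(np.count_nonzero(diff & ((a ^ b) == 2)))
    n_diff = int(np.count_nonzero(diff))
    return PairwiseCounts(
        n_sites=int(np.count_nonzero(valid)),
        n_transitions=transitions,
        n_transversions=n_diff - transitions,
    )


def k2p_distance(counts: PairwiseCounts) -> float:
    """K2P distance in substitutions/site, or NaN where undefined.

    Undefined when there are no compared sites or when saturation makes the
    log argument non-positive (1-2P-Q <= 0 or 1-2Q <= 0).
    """
    if counts.n_sites == 0:
        return math.nan
    p = counts.n_transitions / counts.n_sites
    q = counts.n_transversions / counts.n_sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0  # avoid -0.0 at zero divergence


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric K2P distance matrix with an explicit defined mask.

    ``values[i, j]`` is NaN exactly where ``defined[i, j]`` is False;
    ``overlap`` holds the per-pair count of mutually resolved sites.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    defined: np.ndarray
    overlap: np.ndarray

    def __post_init__(self):
        n = len(self.labels)
        assert self.values.shape == self.defined.shape == self.overlap.shape == (n, n)

    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.labels), k=1)
        return int(np.count_nonzero(~self.defined[iu]))

    def get(self, label_a: str, label_b: str) -> float:
        i, j = self.labels.index(label_a), self.labels.index(label_b)
        return float(self.values[i, j])


def distance_matrix(ds: Dataset, min_overlap: int = DEFAULT_MIN_OVERLAP) -> DistanceMatrix:
    """All-pairs K2P distances for a dataset.

    Pairs with fewer than ``min_overlap`` mutually resolved sites are
    flagged undefined, as are saturated pairs.  The diagonal is 0 and
    always defined.
    """
    labels = ds.accessions
    n = len(labels)
    codes = np.vstack([encode(ds.sequences[a]) for a in labels])
    valid = codes < 4
    values = np.zeros((n, n))
    defined = np.ones((n, n), dtype=bool)
    overlap = np.zeros((n, n), dtype=np.int64)
    overlap[np.diag_indices(n)] = valid.sum(axis=1)
    for i in range(n):
        ai, vi = codes[i], valid[i]
        for j in range(i + 1, n):
            both = vi & valid[j]
            n_sites = int(np.count_nonzero(both))
            diff = both & (ai != codes[j])
            ts = int(np.count_nonzero(diff & ((ai ^ codes[j]) == 2)))
            tv = int(np.count_nonzero(diff)) - ts
            d = k2p_distance(PairwiseCounts(n_sites, ts, tv))
            if n_sites < min_overlap or math.isnan(d):
                d, ok = math.nan, False
            else:
                ok = True
            values[i, j] = values[j, i] = d
            defined[i, j] = defined[j, i] = ok
            overlap[i, j] = overlap[j, i] = n_sites
    return DistanceMatrix(labels=tuple(labels), values=values, defined=defined, overlap=overlap)


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP distance matrix; undefined entries serialised as -1."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for i, label in enumerate(dm.labels):
            row = [
                f"{v:.6f}" if ok else "-1.000000"
                for v, ok in zip(dm.values[i], dm.defined[i])
            ]
            fh.write(label + "  " + " ".join(row) + "\n")


def read_phylip(path) -> DistanceMatrix:
    """Read a square PHYLIP matrix written by :func:`write_phylip`.

    Overlap counts are not serialised in this format and come back as 0.
    """
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        labels, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    values = np.array(rows)
    defined = values >= 0
    values[~defined] = math.nan
    return DistanceMatrix(
        labels=tuple(labels),
        values=values,
        defined=defined,
        overlap=np.zeros((n, n), dtype=np.int64),
    )


def write_long_tsv(dm: DistanceMatrix, path) -> None:
    """Long-form pair table: accessionA, accessionB, distance, n_sites, defined."""
    with open(path, "w") as fh:
        fh.write("accessionA\taccessionB\tdistance\tn_sites\tdefined\n")
        n = len(dm.labels)
        for i in range(n):
            for j in range(i + 1, n):
                d = f"{dm.values[i, j]:.6f}" if dm.defined[i, j] else "NA"
                fh.write(
                    f"{dm.labels[i]}\t{dm.labels[j]}\t{d}\t{dm.overlap[i, j]}\t"
                    f"{int(dm.defined[i, j])}\n"
                )
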