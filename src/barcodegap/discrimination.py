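"""Intra/interspecific distance partitioning and discrimination summaries.

Interspecific comparisons are made one-to-one, between the single
representative accession of each species; intraspecific comparisons pool
all within-species pairs of every species sampled more than once, and
species-level summaries average within species first so unevenly sampled
species do not distort the totals.  From the interspecific distribution we
report the mean/SD/max and the percentage of comparisons exceeding fixed
cutoffs (1% and 2% by default — arbitrary, but standard once no barcoding
gap separates the intra- and interspecific distributions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix
from .io_model import InputError, MetadataTable

DEFAULT_THRESHOLDS = (0.01, 0.02)
DEFAULT_BIN_WIDTH = 0.005


@dataclass(frozen=True)
class DistancePartition:
    """Defined pairwise distances split into inter- and intraspecific sets."""

    interspecific: tuple[tuple[str, str, float], ...]
    intraspecific_by_species: dict[str, list[float]]
    n_undefined_excluded: int

    def interspecific_values(self) -> np.ndarray:
        return np.array([d for _, _, d in self.interspecific])

    def intraspecific_values(self) -> np.ndarray:
        return np.array([d for ds in self.intraspecific_by_species.values() for d in ds])


@dataclass(frozen=True)
class IntraspecificSummary:
    """Species-averaged intraspecific divergence (one value per species)."""

    mean: float
    sd: float
    max: float
    n_accessions: int
    n_species: int


@dataclass(frozen=True)
class GapAssessment:
    """Barcoding-gap diagnostic: margin between the distributions' edges."""

    gap_exists: bool
    gap_margin: float
    bin_edges: np.ndarray
    intra_hist: np.ndarray
    inter_hist: np.ndarray


@dataclass(frozen=True)
class DiscriminationReport:
    """One summary row for one dataset — the machine analogue of a
    barcode-evaluation table row."""

    dataset_name: str
    n_species: int
    aligned_length: int
    n_variable: int
    n_unique: int
    n_unique_fifth: int
    max_id_rate_pct: float
    inter_max: float
    inter_mean: float
    inter_sd: float
    pct_gt_1: float
    pct_gt_2: float
    intra_max: float = math.nan
    intra_mean: float = math.nan
    intra_sd: float = math.nan
    gap_exists: bool | None = None
    gap_margin: float = math.nan

    def __post_init__(self):
        if not (0.0 <= self.pct_gt_2 <= self.pct_gt_1 <= 100.0):
            raise ValueError("threshold fractions must satisfy 0 <= >2% <= >1% <= 100")
        if self.inter_mean > self.inter_max + 1e-12:
            raise ValueError("interspecific mean exceeds maximum")


def _representatives_for(dm: DistanceMatrix, meta: MetadataTable) -> dict[str, str]:
    """Species -> representative among the matrix labels.  Flagged
    representatives win; species with no flagged accession in the matrix
    fall back to the accession with the most resolved sites (ties broken
    lexicographically)."""
    reps: dict[str, str] = {}
    fallback: dict[str, tuple[int, str]] = {}
    diag = {lab: int(dm.overlap[i, i]) for i, lab in enumerate(dm.labels)}
    for lab in dm.labels:
        entry = meta[lab]
        if entry.is_representative:
            reps[entry.species] = lab
        key = (-diag[lab], lab)
        if entry.species not in fallback or key < fallback[entry.species]:
            fallback[entry.species] = key
    for sp, (_, lab) in fallback.items():
        reps.setdefault(sp, lab)
    return reps


def partition_distances(dm: DistanceMatrix, meta: MetadataTable) -> DistancePartition:
    """Split a distance matrix into interspecific (representatives only,
    one per species) and intraspecific (all within-species pairs) sets.
    Undefined distances are excluded and counted."""
    for lab in dm.labels:
        if lab not in meta:
            raise InputError(f"matrix label {lab!r} has no metadata")
    reps = _representatives_for(dm, meta)
    rep_set = set(reps.values())
    index = {lab: i for i, lab in enumerate(dm.labels)}
    inter: list[tuple[str, str, float]] = []
    intra: dict[str, list[float]] = {}
    n_undef = 0
    n = len(dm.labels)
    for i in range(n):
        sp_i = meta.species_of(dm.labels[i])
        for j in range(i + 1, n):
            sp_j = meta.species_of(dm.labels[j])
            if sp_i == sp_j:
                if dm.defined[i, j]:
                    intra.setdefault(sp_i, []).append(float(dm.values[i, j]))
                else:
                    n_undef += 1
            elif dm.labels[i] in rep_set and dm.labels[j] in rep_set:
                if dm.defined[i, j]:
                    a, b = sorted((sp_i, sp_j))
                    inter.append((a, b, float(dm.values[i, j])))
                else:
                    n_undef += 1
    return DistancePartition(
        interspecific=tuple(inter),
        intraspecific_by_species=intra,
        n_undefined_excluded=n_undef,
    )


def _sd(values: np.ndarray) -> float:
    if values.size <= 1:
        return 0.0
    return float(np.std(values, ddof=1))


def intraspecific_summary(part: DistancePartition) -> IntraspecificSummary | None:
    """Species-averaged intraspecific summary, or None if no species has
    two or more accessions.

    Each species contributes its within-species mean once; the reported
    mean and SD are over those per-species means, while the maximum is the
    global maximum over all intraspecific pairs.
    """
    if not part.intraspecific_by_species:
        return None
    per_species = np.array([np.mean(d) for d in part.intraspecific_by_species.values()])
    all_pairs = part.intraspecific_values()
    # k pairs within one species implies C(m,2)=k accessions; recover m
    n_acc = sum(
        round((1 + math.sqrt(1 + 8 * len(d))) / 2)
        for d in part.intraspecific_by_species.values()
    )
    return IntraspecificSummary(
        mean=float(np.mean(per_species)),
        sd=_sd(per_species),
        max=float(np.max(all_pairs)),
        n_accessions=n_acc,
        n_species=len(part.intraspecific_by_species),
    )


def interspecific_summary(part: DistancePartition) -> tuple[float, float, float]:
    """(mean, sd, max) over all defined interspecific distances."""
    values = part.interspecific_values()
    if values.size == 0:
        raise InputError("no defined interspecific comparison")
    return float(np.mean(values)), _sd(values), float(np.max(values))


def fraction_above(part: DistancePartition, threshold: float) -> float:
    """Percentage of interspecific comparisons with distance strictly
    greater than ``threshold`` (a proportion, e.g. 0.01 for 1%)."""
    if threshold < 0:
        raise InputError("threshold must be >= 0")
    values = part.interspecific_values()
    if values.size == 0:
        raise InputError("no defined interspecific comparison")
    return round(100.0 * float(np.count_nonzero(values > threshold)) / values.size, 2)


def barcoding_gap(part: DistancePartition,
                  bin_width: float = DEFAULT_BIN_WIDTH) -> GapAssessment:
    """Assess whether intra- and interspecific distances are separated.

    The margin is min(interspecific) - max(intraspecific); a gap exists
    only when the margin is strictly positive.  Histograms share bins
    starting at 0 with the given width over the pooled range.
    """
    intra = part.intraspecific_values()
    inter = part.interspecific_values()
    if intra.size == 0 or inter.size == 0:
        raise InputError("barcoding gap needs both intra- and interspecific distances")
    margin = float(np.min(inter) - np.max(intra))
    top = max(float(np.max(inter)), float(np.max(intra)))
    n_bins = max(1, int(math.ceil(top / bin_width + 1e-9)))
    edges = np.arange(n_bins + 1) * bin_width
    intra_hist, _ = np.histogram(intra, bins=edges)
    inter_hist, _ = np.histogram(inter, bins=edges)
    return GapAssessment(
        gap_exists=margin > 0,
        gap_margin=margin,
        bin_edges=edges,
        intra_hist=intra_hist,
        inter_hist=inter_hist,
    )


def build_report(ds, part: DistancePartition, hap_missing, hap_fifth,
                 n_variable: int, bin_width: float = DEFAULT_BIN_WIDTH
                 ) -> DiscriminationReport:
    """Assemble a report row from a dataset's computed components.

    ``hap_missing``/``hap_fifth`` are the haplotype partitions under the
    two gap conventions, computed on the same (representatives-only)
    dataset ``ds`` whose distances fed ``part``.
    """
    from .haplotypes import max_id_rate  # local import avoids a cycle

    mean, sd, mx = interspecific_summary(part)
    intra = intraspecific_summary(part)
    kwargs = {}
    if intra is not None:
        kwargs.update(intra_max=intra.max, intra_mean=intra.mean, intra_sd=intra.sd)
        if part.interspecific:
            gap = barcoding_gap(part, bin_width=bin_width)
            kwargs.update(gap_exists=gap.gap_exists, gap_margin=gap.gap_margin)
    return DiscriminationReport(
        dataset_name=ds.name,
        n_species=ds.n_species,
        aligned_length=ds.aligned_length,
        n_variable=n_variable,
        n_unique=hap_missing.n_unique,
        n_unique_fifth=hap_fifth.n_unique,
        max_id_rate_pct=max_id_rate(hap_missing.n_unique, ds.n_species),
        inter_max=mx,
        inter_mean=mean,
        inter_sd=sd,
        pct_gt_1=fraction_above(part, 0.01),
        pct_gt_2=fraction_above(part, 0.02),
        **kwargs,
    )


REPORT_COLUMNS = [
    "Gene Region", "Species", "Aligned Length", "Variable characters",
    "Unique sequences", "% Max ID rate", "Max", "Mean (SD)", "> 1%", "> 2%",
]


def report_row(rep: DiscriminationReport) -> dict[str, str]:
    """Serialise a report in the conventional table layout: distances to 4
    decimals, percentages to 2, the fifth-state unique count in
    parentheses when it differs."""
    unique = str(rep.n_unique)
    if rep.n_unique_fifth != rep.n_unique:
        unique += f" ({rep.n_unique_fifth})"
    return {
        "Gene Region": rep.dataset_name,
        "Species": str(rep.n_species),
        "Aligned Length": str(rep.aligned_length),
        "Variable characters": str(rep.n_variable),
        "Unique sequences": unique,
        "% Max ID rate": f"{rep.max_id_rate_pct:.2f}",
        "Max": f"{rep.inter_max:.4f}",
        "Mean (SD)": f"{rep.inter_mean:.4f} ({rep.inter_sd:.4f})",
        "> 1%": f"{rep.pct_gt_1:.2f}",
        "> 2%": f"{rep.pct_gt_2:.2f}",
    }


def write_report_table(reports, path) -> None:
    import pandas as pd

    pd.DataFrame([report_row(r) for r in reports], columns=REPORT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def write_histogram_tsv(gap: GapAssessment, path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_start\tbin_end\tintra_count\tinter_count\n")
        for k in range(len(gap.intra_hist)):
            fh.write(
                f"{gap.bin_edges[k]:.4f}\t{gap.bin_edges[k + 1]:.4f}\t"
                f"{gap.intra_hist[k]}\t{gap.inter_hist[k]}\n"
            )
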