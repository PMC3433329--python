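"""Orchestration: run the full discrimination protocol over datasets x subsets.

For every requested locus combination the protocol computes, globally and
within each requested clade/region subset: the K2P distance matrix over
all accessions, its partition into intra- and interspecific comparisons,
haplotype counts under both gap conventions on the representatives-only
matrix, and the summary row (species, aligned length, variable sites,
unique sequences, Max ID rate, distance mean/SD/max, threshold fractions,
barcoding-gap diagnostics).
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from .discrimination import (
    DiscriminationReport,
    GapAssessment,
    barcoding_gap,
    build_report,
    partition_distances,
    write_histogram_tsv,
    write_report_table,
)
from .distances import DEFAULT_MIN_OVERLAP, distance_matrix
from .haplotypes import GapMode, collapse_haplotypes, count_variable_sites
from .io_model import (
    AlignmentSet,
    Dataset,
    EmptyDatasetError,
    InputError,
    MetadataTable,
    build_dataset,
    choose_representatives,
    subset_dataset,
)
from .synthetic_data import SimulationConfig, SimulatedTruth, simulate_bundle

logger = logging.getLogger("barcodegap")

DEFAULT_BIN_WIDTH = 0.005


@dataclass(frozen=True)
class RunConfig:
    """What to evaluate: locus combinations, subsets, and numeric knobs."""

    combinations: tuple[tuple[str, ...], ...]
    subsets: tuple[tuple[str, str], ...] = ()  # (kind, name); kind in {clade, region}
    thresholds: tuple[float, ...] = (0.01, 0.02)
    min_overlap: int = DEFAULT_MIN_OVERLAP
    bin_width: float = DEFAULT_BIN_WIDTH
    out_dir: Path | None = None

    def __post_init__(self):
        if any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be strictly positive")
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be sorted ascending")


def standard_combinations(core: tuple[str, str] = ("rbcL", "matK"),
                          supplements: tuple[str, ...] = ("trnH-psbA", "nrITS"),
                          singletons: tuple[str, ...] = (
                              "matK", "rbcL", "rpl32-trnL", "trnH-psbA", "trnK", "nrITS"),
                          ) -> tuple[tuple[str, ...], ...]:
    """The standard nine datasets: each locus alone, the core two-locus
    barcode, and core + each supplementary barcode."""
    combos = [(s,) for s in singletons]
    combos.append(core)
    combos.extend(core + (s,) for s in supplements)
    return tuple(combos)


def representatives_dataset(ds: Dataset, meta: MetadataTable) -> Dataset:
    """Restrict a dataset to one representative accession per species:
    flagged accessions where present, otherwise the fewest-missing-
    characters fallback for species whose flagged accession dropped out."""
    flagged = [a for a in ds.accessions if meta[a].is_representative]
    covered = {meta.species_of(a) for a in flagged}
    rest = [a for a in ds.accessions if meta.species_of(a) not in covered]
    keep = set(flagged) | choose_representatives(ds.sequences, meta, rest)
    accs = tuple(a for a in ds.accessions if a in keep)
    return replace(
        ds,
        accessions=accs,
        sequences={a: ds.sequences[a] for a in accs},
        n_species=len({meta.species_of(a) for a in accs}),
    )


@dataclass(frozen=True)
class DatasetEvaluation:
    """Report row plus the intermediates a caller may want to inspect."""

    report: DiscriminationReport
    gap: GapAssessment | None
    n_undefined_pairs: int


def evaluate_dataset(ds_all: Dataset, meta: MetadataTable,
                     min_overlap: int = DEFAULT_MIN_OVERLAP,
                     bin_width: float = DEFAULT_BIN_WIDTH) -> DatasetEvaluation:
    """Full protocol on one dataset (all accessions of one locus set)."""
    dm = distance_matrix(ds_all, min_overlap=min_overlap)
    part = partition_distances(dm, meta)
    ds_repr = representatives_dataset(ds_all, meta)
    hap_missing = collapse_haplotypes(ds_repr, GapMode.GAP_AS_MISSING)
    hap_fifth = collapse_haplotypes(ds_repr, GapMode.GAP_AS_FIFTH_STATE)
    n_var = count_variable_sites(ds_repr)
    report = build_report(ds_repr, part, hap_missing, hap_fifth, n_var,
                          bin_width=bin_width)
    gap = None
    if part.intraspecific_by_species and part.interspecific:
        gap = barcoding_gap(part, bin_width=bin_width)
    return DatasetEvaluation(report=report, gap=gap,
                             n_undefined_pairs=dm.n_undefined_pairs())


@dataclass
class EvaluationResult:
    """All rows of one run, keyed by (dataset name, subset label)."""

    evaluations: dict[tuple[str, str], DatasetEvaluation] = field(default_factory=dict)
    skipped: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def reports(self) -> dict[tuple[str, str], DiscriminationReport]:
        return {k: e.report for k, e in self.evaluations.items()}

    def table(self, subset_label: str = "global") -> list[DiscriminationReport]:
        return [e.report for (_, lab), e in self.evaluations.items()
                if lab == subset_label]


def run_evaluate(cfg: RunConfig, aln: AlignmentSet) -> EvaluationResult:
    """Evaluate every locus combination globally and within every subset.

    Empty subsets are skipped (and logged), not fatal.  When
    ``cfg.out_dir`` is set, writes one report table per subset label, one
    histogram TSV per dataset where intraspecific pairs exist, and a run
    log recording exclusions and skips.
    """
    meta = aln.metadata
    result = EvaluationResult()
    subset_specs: list[tuple[str, str, str]] = [("global", "", "global")]
    subset_specs += [(kind, name, f"{kind}:{name}") for kind, name in cfg.subsets]

    for loci in cfg.combinations:
        ds_all = build_dataset(aln, list(loci))
        for kind, name, label in subset_specs:
            try:
                ds_sub = ds_all if kind == "global" else subset_dataset(
                    ds_all, meta, name, kind=kind)
                ev = evaluate_dataset(ds_sub, meta, min_overlap=cfg.min_overlap,
                                      bin_width=cfg.bin_width)
            except (EmptyDatasetError, InputError, ValueError) as exc:
                logger.warning("skipping %s / %s: %s", ds_all.name, label, exc)
                result.skipped.append((ds_all.name, label, str(exc)))
                continue
            result.evaluations[(ds_all.name, label)] = ev
            logger.info("evaluated %s / %s: %d species, Max ID %.2f%%",
                        ds_all.name, label, ev.report.n_species,
                        ev.report.max_id_rate_pct)

    if cfg.out_dir is not None:
        _write_bundle(cfg, result)
    return result


def _safe_name(label: str) -> str:
    return label.replace(":", "_").replace("+", "-").replace(" ", "_")


def _write_bundle(cfg: RunConfig, result: EvaluationResult) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = ["global"] + [f"{k}:{n}" for k, n in cfg.subsets]
    for label in labels:
        rows = result.table(label)
        if rows:
            write_report_table(rows, out / f"report_{_safe_name(label)}.tsv")
    for (ds_name, label), ev in result.evaluations.items():
        if ev.gap is not None and label == "global":
            write_histogram_tsv(ev.gap, out / f"hist_{_safe_name(ds_name)}.tsv")
    with open(out / "run.log", "a") as fh:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        fh.write(f"[{stamp}] evaluated {len(result.evaluations)} dataset/subset rows; "
                 f"skipped {len(result.skipped)}\n")
        for key, ev in sorted(result.evaluations.items()):
            if ev.n_undefined_pairs:
                fh.write(f"[{stamp}] {key[0]} / {key[1]}: "
                         f"{ev.n_undefined_pairs} undefined distance pairs excluded\n")
        for ds_name, label, msg in result.skipped:
            fh.write(f"[{stamp}] skipped {ds_name} / {label}: {msg}\n")


def run_simulate(cfg: SimulationConfig, out_dir: str | Path
                 ) -> tuple[AlignmentSet, SimulatedTruth]:
    """Generate and write a synthetic input bundle; logs a summary."""
    aln, truth = simulate_bundle(cfg, out_dir=out_dir)
    logger.info("simulated %d species (%d accessions) x %d loci into %s",
                cfg.n_species, len(aln.metadata), len(cfg.loci), out_dir)
    return aln, truth


def plot_histograms(gap: GapAssessment, path, title: str = "") -> None:
    """Optional PNG of the intra/inter distance histograms."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = (gap.bin_edges[:-1] + gap.bin_edges[1:]) / 2.0
    width = gap.bin_edges[1] - gap.bin_edges[0]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(centers, gap.intra_hist, width=width * 0.9, color="black",
           label="intraspecific")
    ax.bar(centers, gap.inter_hist, width=width * 0.9, color="seagreen",
           alpha=0.6, label="interspecific")
    ax.set_xlabel("K2P distance (substitutions/site)")
    ax.set_ylabel("comparisons")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
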