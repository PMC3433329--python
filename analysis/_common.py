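"""Shared plumbing for the numbered analysis scripts."""

from pathlib import Path

from barcodegap.io_model import AlignmentSet, read_fasta_alignment, read_metadata
from barcodegap.synthetic_data import DEFAULT_LOCI

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIM_DIR = RESULTS / "simulated_input"
LOCUS_NAMES = [l.name for l in DEFAULT_LOCI]


def load_bundle(sim_dir: Path = SIM_DIR) -> AlignmentSet:
    """Load the simulated input bundle written by 01_simulate.py."""
    if not (sim_dir / "metadata.tsv").exists():
        raise SystemExit(
            f"no simulated bundle under {sim_dir}; run analysis/01_simulate.py first"
        )
    loci = {
        name: tuple(read_fasta_alignment(sim_dir / f"{name}.fasta", name))
        for name in LOCUS_NAMES
    }
    meta = read_metadata(sim_dir / "metadata.tsv")
    return AlignmentSet(loci=loci, metadata=meta)
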