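import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from barcodegap.io_model import (
    AlignmentSet,
    MetadataTable,
    SampleMetadata,
    SequenceRecord,
)
from barcodegap.synthetic_data import (
    CladeConfig,
    LocusConfig,
    SimulationConfig,
    simulate_bundle,
)


def make_alignment(loci: dict[str, dict[str, str]],
                   meta_rows: list[tuple]) -> AlignmentSet:
    """Build an AlignmentSet from {locus: {accession: residues}} plus
    (accession, species, clade_path, region, rep) metadata rows."""
    records = {
        locus: tuple(
            SequenceRecord(accession_id=acc, locus=locus, residues=res)
            for acc, res in seqs.items()
        )
        for locus, seqs in loci.items()
    }
    meta = MetadataTable(
        SampleMetadata(acc, sp, tuple(cp), region, bool(rep))
        for acc, sp, cp, region, rep in meta_rows
    )
    return AlignmentSet(loci=records, metadata=meta)


@pytest.fixture
def toy_alignment():
    """Two loci, three species in two clades, one species with two accessions."""
    loci = {
        "locA": {
            "x1": "ACGTACGTAC",
            "y1": "ACGTACGTAA",
            "y2": "ACGTACGTAA",
            "z1": "ACTTACGCAC",
        },
        "locB": {
            "x1": "GGGGCCCC",
            "y1": "GGGGCCCT",
            "z1": "GGAGCCTT",
        },
    }
    meta_rows = [
        ("x1", "spX", ["Root", "cladeA"], "north", 1),
        ("y1", "spY", ["Root", "cladeA"], "north", 1),
        ("y2", "spY", ["Root", "cladeA"], "north", 0),
        ("z1", "spZ", ["Root", "cladeB"], "south", 1),
    ]
    return make_alignment(loci, meta_rows)


@pytest.fixture(scope="session")
def small_sim():
    """Small clade-structured simulation shared across tests: 2 clades x 5
    species, 2 loci with a 4x rate contrast, gaps and missing data on."""
    cfg = SimulationConfig(
        clades=(CladeConfig("cladeA", 5, region="regionX"), CladeConfig("cladeB", 5)),
        loci=(LocusConfig("slow", 400, 0.01), LocusConfig("fast", 300, 0.04)),
        intraspecific_depth=0.02,
        seed=7,
    )
    aln, truth = simulate_bundle(cfg)
    return cfg, aln, truth
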