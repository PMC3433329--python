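"""Data model and IO: aligned FASTA loci, sample metadata, dataset assembly.

Sequences arrive already aligned, one FASTA per locus.  A metadata TSV maps
each accession to its species, its clade path (outermost to innermost),
an optional region tag, and a flag marking the single representative
accession per species used for interspecific comparisons.  Datasets are
assembled by selecting loci (optionally concatenated, complete cases only)
and optionally restricting to representatives, a clade, or a region.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

MISSING = "N"
GAP = "-"
#: IUPAC nucleotide one-letter codes accepted in alignments (after the
#: '?' -> 'N' normalisation applied on read).
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")
AMBIGUITY_CHARS = frozenset("RYSWKMBDHV")
CLADE_DELIMITER = ";"

METADATA_COLUMNS = ["accession", "species", "clade_path", "region", "representative"]


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class AlignmentError(InputError):
    """Sequences that should be aligned have unequal lengths."""


class EmptyDatasetError(InputError):
    """A dataset or subset operation left no accessions."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence of one locus for one accession."""

    accession_id: str
    locus: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-accession sample annotations.

    ``clade_path`` runs outermost to innermost (the first element is the
    root clade); ``region`` is a flat tag, not derived from coordinates.
    """

    accession_id: str
    species: str
    clade_path: tuple[str, ...]
    region: str | None = None
    is_representative: bool = False


class MetadataTable:
    """Collection of :class:`SampleMetadata`, indexed by accession."""

    def __init__(self, entries: Iterable[SampleMetadata]):
        self._by_accession: dict[str, SampleMetadata] = {}
        for e in entries:
            if e.accession_id in self._by_accession:
                raise InputError(f"duplicate accession {e.accession_id!r} in metadata")
            if not e.species:
                raise InputError(f"accession {e.accession_id!r} has no species")
            if not e.clade_path:
                raise InputError(f"accession {e.accession_id!r} has empty clade_path")
            self._by_accession[e.accession_id] = e

    def __len__(self) -> int:
        return len(self._by_accession)

    def __iter__(self):
        return iter(self._by_accession.values())

    def __contains__(self, accession_id: str) -> bool:
        return accession_id in self._by_accession

    def __getitem__(self, accession_id: str) -> SampleMetadata:
        try:
            return self._by_accession[accession_id]
        except KeyError:
            raise InputError(f"accession {accession_id!r} not present in metadata") from None

    def species_of(self, accession_id: str) -> str:
        return self[accession_id].species

    def accessions(self) -> list[str]:
        return list(self._by_accession)

    def species(self) -> set[str]:
        return {e.species for e in self}

    def representatives(self) -> dict[str, str]:
        """Map species -> representative accession; errors if a species has
        zero or several flagged representatives."""
        reps: dict[str, str] = {}
        for e in self:
            if e.is_representative:
                if e.species in reps:
                    raise InputError(
                        f"species {e.species!r} has multiple representative accessions"
                    )
                reps[e.species] = e.accession_id
        return reps


@dataclass(frozen=True)
class AlignmentSet:
    """Per-locus aligned records plus the metadata table they refer to."""

    loci: Mapping[str, tuple[SequenceRecord, ...]]
    metadata: MetadataTable

    def __post_init__(self):
        for locus, records in self.loci.items():
            lengths = {len(r) for r in records}
            if len(lengths) > 1:
                raise AlignmentError(
                    f"locus {locus!r} has unequal alignment lengths {sorted(lengths)}"
                )
            seen: set[str] = set()
            for r in records:
                if r.accession_id in seen:
                    raise InputError(
                        f"accession {r.accession_id!r} duplicated in locus {locus!r}"
                    )
                seen.add(r.accession_id)
                if r.accession_id not in self.metadata:
                    raise InputError(
                        f"accession {r.accession_id!r} of locus {locus!r} missing from metadata"
                    )

    def locus_length(self, locus: str) -> int:
        records = self.loci[locus]
        return len(records[0]) if records else 0


@dataclass(frozen=True)
class Dataset:
    """One analysis-ready matrix: a (possibly concatenated) set of loci
    restricted to complete-case accessions.

    ``sequences`` maps accession -> concatenated residue string; the
    iteration order of ``accessions`` is the row order of every matrix
    derived downstream.
    """

    name: str
    accessions: tuple[str, ...]
    sequences: Mapping[str, str]
    n_species: int
    aligned_length: int

    def __len__(self) -> int:
        return len(self.accessions)

    def residues(self) -> list[str]:
        return [self.sequences[a] for a in self.accessions]


def _normalise_residues(raw: str, context: str) -> str:
    residues = raw.upper().replace("?", MISSING)
    bad = set(residues) - IUPAC_CHARS
    if bad:
        raise InputError(
            f"{context}: non-IUPAC character(s) {sorted(bad)!r} in sequence"
        )
    return residues


def read_fasta_alignment(path: str | Path, locus: str) -> list[SequenceRecord]:
    """Read one locus alignment from FASTA.

    Residues are uppercased; '?' and 'N' are normalised to the single
    missing symbol 'N'.  All sequences must have equal length.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = _normalise_residues(str(rec.seq), f"{path}:{rec.id}")
        records.append(SequenceRecord(accession_id=rec.id, locus=locus, residues=residues))
    if not records:
        raise InputError(f"{path}: empty FASTA for locus {locus!r}")
    lengths = {len(r) for r in records}
    if len(lengths) > 1:
        raise AlignmentError(
            f"{path}: unequal sequence lengths {sorted(lengths)} for locus {locus!r}"
        )
    return records


def write_fasta_alignment(records: Sequence[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.accession_id, description="")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_metadata(path: str | Path, clade_delimiter: str = CLADE_DELIMITER) -> MetadataTable:
    """Read the metadata TSV (columns: accession, species, clade_path,
    region, representative)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(METADATA_COLUMNS) - set(df.columns)
    if missing_cols:
        raise InputError(f"{path}: metadata is missing column(s) {sorted(missing_cols)}")
    entries = []
    for row in df.itertuples(index=False):
        clade_path = tuple(p for p in str(row.clade_path).split(clade_delimiter) if p)
        if not clade_path:
            raise InputError(f"{path}: accession {row.accession!r} has empty clade_path")
        if not row.species:
            raise InputError(f"{path}: accession {row.accession!r} has no species")
        rep = str(row.representative).strip()
        if rep not in {"0", "1"}:
            raise InputError(
                f"{path}: accession {row.accession!r} representative flag {rep!r} not in {{0,1}}"
            )
        entries.append(
            SampleMetadata(
                accession_id=str(row.accession),
                species=str(row.species),
                clade_path=clade_path,
                region=str(row.region) or None,
                is_representative=rep == "1",
            )
        )
    return MetadataTable(entries)


def write_metadata(meta: MetadataTable, path: str | Path,
                   clade_delimiter: str = CLADE_DELIMITER) -> None:
    rows = [
        {
            "accession": e.accession_id,
            "species": e.species,
            "clade_path": clade_delimiter.join(e.clade_path),
            "region": e.region or "",
            "representative": int(e.is_representative),
        }
        for e in meta
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def clade_paths_from_newick(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Derive per-species clade paths from a Newick tree whose internal
    nodes are labelled with clade names.

    For each leaf, the path is the sequence of labelled internal nodes
    from the root down to the leaf (unlabelled internal nodes are
    skipped).  Only a convenience for populating the metadata table; the
    pipeline itself never infers trees.
    """
    import dendropy

    tree = dendropy.Tree.get(path=str(path), schema="newick")
    paths: dict[str, tuple[str, ...]] = {}
    for leaf in tree.leaf_node_iter():
        labels = []
        node = leaf.parent_node
        while node is not None:
            if node.label:
                labels.append(node.label)
            node = node.parent_node
        name = leaf.taxon.label if leaf.taxon else leaf.label
        paths[name] = tuple(reversed(labels))
    return paths


def _quality(residues: str) -> int:
    """Number of gap/missing/ambiguous characters (lower is better)."""
    return sum(1 for c in residues if c == GAP or c == MISSING or c in AMBIGUITY_CHARS)


def choose_representatives(sequences: Mapping[str, str], meta: MetadataTable,
                           accessions: Iterable[str]) -> set[str]:
    """Default representative rule when no flags are set: per species, the
    accession with the fewest gap/missing/ambiguous characters, ties broken
    lexicographically by accession id."""
    best: dict[str, tuple[int, str]] = {}
    for acc in accessions:
        key = (_quality(sequences[acc]), acc)
        sp = meta.species_of(acc)
        if sp not in best or key < best[sp]:
            best[sp] = key
    return {acc for _, acc in best.values()}


def build_dataset(aln: AlignmentSet, loci: Sequence[str],
                  representatives_only: bool = False,
                  name: str | None = None) -> Dataset:
    """Assemble a dataset by concatenating loci in the given order.

    Only complete cases are kept: an accession enters a multi-locus dataset
    only if it has a sequence for every requested locus.  With
    ``representatives_only``, keep the flagged accession per species
    (falling back to the fewest-missing-characters rule if no flags exist).
    """
    for locus in loci:
        if locus not in aln.loci:
            raise InputError(f"requested locus {locus!r} not in alignment set")
    per_locus = {locus: {r.accession_id: r.residues for r in aln.loci[locus]} for locus in loci}
    common = set(per_locus[loci[0]])
    for locus in loci[1:]:
        common &= set(per_locus[locus])
    # preserve first-locus record order for determinism
    ordered = [r.accession_id for r in aln.loci[loci[0]] if r.accession_id in common]
    sequences = {acc: "".join(per_locus[locus][acc] for locus in loci) for acc in ordered}

    if representatives_only:
        flagged = {a for a in ordered if aln.metadata[a].is_representative}
        if flagged:
            keep = flagged
        else:
            keep = choose_representatives(sequences, aln.metadata, ordered)
        ordered = [a for a in ordered if a in keep]
        sequences = {a: sequences[a] for a in ordered}

    if not ordered:
        raise EmptyDatasetError(
            f"no accession carries all of {list(loci)!r}"
            + (" among representatives" if representatives_only else "")
        )
    n_species = len({aln.metadata.species_of(a) for a in ordered})
    aligned_length = sum(aln.locus_length(locus) for locus in loci)
    return Dataset(
        name=name or "+".join(loci),
        accessions=tuple(ordered),
        sequences=sequences,
        n_species=n_species,
        aligned_length=aligned_length,
    )


def subset_dataset(ds: Dataset, meta: MetadataTable, selector: str,
                   kind: str = "clade") -> Dataset:
    """Restrict a dataset to a clade (matched anywhere on the clade path)
    or to a region (matched exactly)."""
    if kind == "clade":
        keep = [a for a in ds.accessions if selector in meta[a].clade_path]
    elif kind == "region":
        keep = [a for a in ds.accessions if meta[a].region == selector]
    else:
        raise ValueError(f"unknown selector kind {kind!r}")
    if not keep:
        raise EmptyDatasetError(f"{kind} selector {selector!r} matches no accession of {ds.name!r}")
    sequences = {a: ds.sequences[a] for a in keep}
    n_species = len({meta.species_of(a) for a in keep})
    return replace(
        ds,
        name=f"{ds.name}[{kind}:{selector}]",
        accessions=tuple(keep),
        sequences=sequences,
        n_species=n_species,
    )
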