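"""In-memory model of a curated reference protein database.

Mirrors what the pipeline needs from a STRING-like resource: protein
sequences with orthologous-group (COG) membership and a species label.
Proteins assigned to multiple COGs are products of gene fusion (or similar)
and are excluded when collecting members to build a gene profile, but they
remain reciprocal-search targets: the reciprocal best-hit stage runs
against the full database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = ["ProteinRecord", "ReferenceDB", "build_refdb", "cog_members"]


@dataclass(frozen=True)
class ProteinRecord:
    """A reference protein with its COG membership and source species."""

    protein_id: str
    species: str
    cogs: frozenset[str]
    sequence: str

    def __post_init__(self) -> None:
        if not self.cogs:
            raise ValueError(f"{self.protein_id}: needs at least one COG")
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")

    @property
    def is_fused(self) -> bool:
        return len(self.cogs) > 1


@dataclass
class ReferenceDB:
    records: dict[str, ProteinRecord] = field(default_factory=dict)
    cog_index: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        """Check that cog_index is exactly the inverse of record COG sets."""
        inverse: dict[str, set[str]] = {}
        for pid, rec in self.records.items():
            for cog in rec.cogs:
                inverse.setdefault(cog, set()).add(pid)
        indexed = {cog: set(ids) for cog, ids in self.cog_index.items()}
        if inverse != indexed:
            raise ValueError("cog_index is not the inverse of record COG sets")

    def to_tables(self) -> tuple[list[SeqRecord], list[tuple[str, str, str]]]:
        """Serialize back to (protein FASTA records, cog_table rows)."""
        proteins = [
            SeqRecord(Seq(rec.sequence), id=pid, description="")
            for pid, rec in sorted(self.records.items())
        ]
        rows = [
            (pid, cog, rec.species)
            for pid, rec in sorted(self.records.items())
            for cog in sorted(rec.cogs)
        ]
        return proteins, rows


def build_refdb(proteins, cog_table) -> ReferenceDB:
    """Assemble a ReferenceDB from protein records and COG membership rows.

    Parameters
    ----------
    proteins:
        Sequence records (e.g. from :func:`ihat.formats_io.read_fasta`).
    cog_table:
        Rows of (protein_id, cog_id, species). Rows referencing unknown
        protein ids are ignored with a logged count; proteins with no row
        are dropped with a logged count.

    Raises
    ------
    ValueError
        If two rows assign different species to the same protein id.
    """
    seqs: dict[str, str] = {}
    for rec in proteins:
        if rec.id in seqs:
            raise ValueError(f"duplicate protein id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)

    cogs_of: dict[str, set[str]] = {}
    species_of: dict[str, str] = {}
    n_unknown = 0
    for pid, cog, species in cog_table:
        if pid not in seqs:
            n_unknown += 1
            continue
        prev = species_of.get(pid)
        if prev is not None and prev != species:
            raise ValueError(
                f"species conflict for {pid!r}: {prev!r} vs {species!r}"
            )
        species_of[pid] = species
        cogs_of.setdefault(pid, set()).add(cog)
    if n_unknown:
        logger.warning("ignored %d cog_table rows with unknown protein ids", n_unknown)

    n_dropped = len(seqs) - len(cogs_of)
    if n_dropped:
        logger.warning("dropped %d proteins absent from the cog_table", n_dropped)

    db = ReferenceDB()
    for pid in sorted(cogs_of):
        rec = ProteinRecord(
            protein_id=pid,
            species=species_of[pid],
            cogs=frozenset(cogs_of[pid]),
            sequence=seqs[pid],
        )
        db.records[pid] = rec
        for cog in rec.cogs:
            db.cog_index.setdefault(cog, []).append(pid)
    for cog in db.cog_index:
        db.cog_index[cog].sort()
    db.validate()
    return db


def cog_members(db: ReferenceDB, cog: str, exclude_fused: bool = True):
    """Return the member proteins of a COG, lexicographically by id.

    With ``exclude_fused`` (the default, used at profile-building time),
    proteins assigned to more than one COG — gene-fusion products — are
    rejected and only members whose COG set is exactly ``{cog}`` remain.
    Unknown COGs yield an empty list.
    """
    members = [db.records[pid] for pid in db.cog_index.get(cog, [])]
    if exclude_fused:
        members = [m for m in members if m.cogs == frozenset({cog})]
    return members
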