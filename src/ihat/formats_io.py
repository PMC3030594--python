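"""Readers and writers for the pipeline's external artifacts.

Everything the pipeline touches on disk is plain text: FASTA (nucleotide
and protein), tab-separated gene lists and COG membership tables, nutrient
measurement records, per-sample abundance tables, and the per-gene/database
annotation report. FASTA parsing is delegated to Biopython; the tabular
dialects are defined here and kept byte-stable so reports diff cleanly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneSpec",
    "Report",
    "read_fasta",
    "write_fasta",
    "read_gene_list",
    "read_db_list",
    "read_cog_table",
    "read_nutrient_table",
    "read_samples_table",
    "write_report",
]

#: Characters accepted per declared alphabet. Ambiguity codes are passed
#: through untouched ('N' for nucleotide, 'X' for protein); '*' is accepted
#: in protein records because translated candidate extracts may contain
#: stop codons.
ALPHABETS = {
    "nucleotide": set("ACGTN"),
    "protein": set("ACDEFGHIKLMNPQRSTVWYX*"),
}

FASTA_WRAP = 80


@dataclass(frozen=True)
class GeneSpec:
    """One query gene: its name, COG and the name of its whole-gene model."""

    gene_name: str
    cog_id: str
    model_name: str

    def __post_init__(self) -> None:
        if not (self.gene_name and self.cog_id and self.model_name):
            raise ValueError("GeneSpec fields must be non-empty")


@dataclass
class Report:
    """Per gene/database result: a summary header plus the two call lists.

    ``annotated`` holds calls that passed the reciprocal COG check,
    ``failed`` holds candidates whose best reciprocal hit belonged to a
    different COG (heterofunctional homologs).
    """

    gene_name: str
    database_id: str
    n_searched: int
    annotated: list = field(default_factory=list)
    failed: list = field(default_factory=list)

    @property
    def n_candidates(self) -> int:
        return len(self.annotated) + len(self.failed)

    def validate(self) -> None:
        for call in self.annotated:
            if not call.cog_match:
                raise ValueError("annotated call without COG match")
        for call in self.failed:
            if call.cog_match:
                raise ValueError("failed call with COG match")


def read_fasta(path, alphabet: str) -> list[SeqRecord]:
    """Read a FASTA file, upper-casing sequences and validating residues.

    Parameters
    ----------
    path:
        File to read.
    alphabet:
        ``"nucleotide"`` or ``"protein"``; characters outside the alphabet
        (plus its ambiguity codes) are rejected.

    Raises
    ------
    ValueError
        On duplicate record ids or out-of-alphabet characters.
    """
    allowed = ALPHABETS[alphabet]
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - allowed
        if bad:
            raise ValueError(
                f"record {rec.id!r}: characters {sorted(bad)} outside "
                f"{alphabet} alphabet"
            )
        records.append(SeqRecord(Seq(seq), id=rec.id, description=rec.description))
    if not records:
        warnings.warn(f"empty FASTA file: {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    """Write records as FASTA wrapped at 80 columns, preserving order."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description not in ("", rec.id) else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            seq = str(rec.seq)
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_gene_list(path) -> list[GeneSpec]:
    """Parse a tab-separated gene list: gene name, COG id, model name.

    Lines starting with ``#`` are comments. Gene names must be unique.
    """
    genes: list[GeneSpec] = []
    names: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(
                f"{path}:{lineno}: expected 3 tab-separated fields, "
                f"got {len(fields)}"
            )
        spec = GeneSpec(*[f.strip() for f in fields])
        if spec.gene_name in names:
            raise ValueError(f"{path}:{lineno}: duplicate gene {spec.gene_name!r}")
        names.add(spec.gene_name)
        genes.append(spec)
    return genes


def read_db_list(path) -> list[Path]:
    """Read a database list: one FASTA path per line ('#' comments allowed)."""
    return [Path(line.strip()) for _, line in _data_lines(path)]


def read_cog_table(path) -> list[tuple[str, str, str]]:
    """Read COG membership rows: protein_id, cog_id, species (tab-separated)."""
    rows = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(
                f"{path}:{lineno}: expected 3 tab-separated fields, "
                f"got {len(fields)}"
            )
        rows.append(tuple(f.strip() for f in fields))
    return rows


def read_nutrient_table(path, variable: str | None = None) -> list[tuple[str, float]]:
    """Read nutrient measurement records.

    The file is tab-separated with columns site, variable, value. When
    ``variable`` is given, only matching rows are returned, as
    (site, value) pairs.
    """
    records = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected site\\tvariable\\tvalue")
        site, var, value = (f.strip() for f in fields)
        if variable is not None and var != variable:
            continue
        records.append((site, float(value)))
    return records


def read_samples_table(path):
    """Read a per-sample abundance table into SampleAbundance objects.

    Required columns: ``sample_id``, ``n_sequences``, ``marker_count``.
    Columns named ``gene_<name>`` are per-gene homolog counts; any other
    numeric column is treated as an environmental covariate.
    """
    from .abundance_stats import SampleAbundance

    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "n_sequences", "marker_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        gene_counts = {
            col[len("gene_") :]: int(row[col])
            for col in df.columns
            if col.startswith("gene_")
        }
        covariates = {
            col: float(row[col])
            for col in df.columns
            if col not in required and not col.startswith("gene_")
        }
        samples.append(
            SampleAbundance(
                sample_id=str(row["sample_id"]),
                n_sequences=int(row["n_sequences"]),
                gene_counts=gene_counts,
                marker_count=int(row["marker_count"]),
                covariates=covariates,
            )
        )
    return samples


def _call_line(call) -> str:
    cogs = ",".join(sorted(call.best_hit_cogs)) if call.best_hit_cogs else "-"
    return "\t".join(
        [
            call.fragment_id,
            call.best_subject_id or "-",
            call.species or "-",
            cogs,
            f"{call.e_value:.2e}",
            f"{call.bit_score:.1f}",
        ]
    )


def write_report(report: Report, path) -> None:
    """Write the annotation report.

    Dialect: '#'-prefixed summary header, then an ``[ANNOTATED]`` and a
    ``[FAILED]`` section with one tab-separated line per call
    (fragment_id, best_subject_id, species, best_hit_cogs, e_value,
    bit_score). E-values use scientific notation with 3 significant
    digits. Output is byte-identical for identical input.
    """
    report.validate()
    lines = [
        f"# gene: {report.gene_name}",
        f"# database: {report.database_id}",
        f"# sequences_searched: {report.n_searched}",
        f"# candidates: {report.n_candidates}",
        f"# annotated: {len(report.annotated)}",
        f"# failed: {len(report.failed)}",
        "[ANNOTATED]",
        *[_call_line(c) for c in report.annotated],
        "[FAILED]",
        *[_call_line(c) for c in report.failed],
    ]
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
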