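"""Evaluation apparatus: exact-model read sampling with locus ground truth,
a synthetic toy world with planted gene families, accuracy scoring, and
the expect-value cutoff sweep.

The sampler draws error-free fragments (literal genome substrings) of a
fixed length uniformly from both strands — the exact sampling model, with
ceil(coverage * genome_length / fragment_length) fragments per dataset.
Ground truth is assigned by full containment: a fragment counts as sampled
from a gene only if it lies entirely between the gene's start and end
loci, which avoids bias from differential conservation at gene ends (and
means a gene shorter than the fragment length can contribute no truth
fragments at all).

The toy world plants protein families built from a shared domain library
into a synthetic genome, including the two hard cases any annotator must
face: a decoy paralog sharing one conserved domain with a target family
(the ABC-transporter/sensor-kinase scenario, where plain cutoff searches
produce false positives), and a target gene absent from the genome (where
the correct answer is zero calls).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import PROTEIN_ALPHABET, SubstitutionMatrix
from .formats_io import GeneSpec, Report
from .refdb import ReferenceDB, build_refdb

__all__ = [
    "GeneLocus",
    "SimulationSpec",
    "Fragment",
    "EvaluationResult",
    "ToyWorld",
    "sample_fragments",
    "label_truth",
    "make_toy_world",
    "evaluate_calls",
    "cutoff_sweep",
    "baseline_best_evalues",
    "fragments_to_records",
    "records_to_fragments",
    "write_loci",
]

#: Most-used codon per amino acid (bacterial code, table 11) for
#: reverse-translating toy proteins into the synthetic genome.
PREFERRED_CODON = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}
STOP_CODON = "TAA"


@dataclass(frozen=True)
class GeneLocus:
    """A gene's position on the genome, 1-based inclusive."""

    gene_name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"{self.gene_name}: invalid locus coordinates")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_name}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SimulationSpec:
    """Exact-model sampling parameters."""

    fragment_length: int = 350
    coverage: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fragment_length < 1 or self.coverage <= 0:
            raise ValueError("fragment_length and coverage must be positive")


@dataclass(frozen=True)
class Fragment:
    fragment_id: str
    sequence: str
    source_start: int
    source_end: int
    source_strand: str
    truth_gene: str | None = None


@dataclass(frozen=True)
class EvaluationResult:
    """Per-gene accuracy bookkeeping against locus ground truth."""

    gene_name: str
    n_truth: int
    n_called: int
    n_correct: int
    n_false: int
    sensitivity: float | None


def sample_fragments(genome, spec: SimulationSpec) -> list[Fragment]:
    """Sample ceil(coverage*L/length) exact fragments from a genome record.

    Start positions are uniform on [1, L - length + 1] with replacement;
    the strand is chosen uniformly and minus-strand fragments are
    reverse-complemented. There is no error model.
    """
    seq = str(genome.seq) if hasattr(genome, "seq") else str(genome)
    L = len(seq)
    ell = spec.fragment_length
    if ell > L:
        raise ValueError(f"fragment length {ell} exceeds genome length {L}")
    n = math.ceil(spec.coverage * L / ell)
    rng = np.random.default_rng([spec.seed, 303])
    starts = rng.integers(1, L - ell + 2, size=n)
    strands = rng.integers(0, 2, size=n)
    width = max(6, len(str(n)))
    fragments = []
    for i, (s, minus) in enumerate(zip(starts, strands)):
        s = int(s)
        sub = seq[s - 1 : s - 1 + ell]
        if minus:
            sub = str(Seq(sub).reverse_complement())
        fragments.append(
            Fragment(
                fragment_id=f"frag{i:0{width}d}",
                sequence=sub,
                source_start=s,
                source_end=s + ell - 1,
                source_strand="-" if minus else "+",
            )
        )
    return fragments


def label_truth(fragments, loci) -> list[Fragment]:
    """Assign ground truth by full containment within a gene locus.

    ``truth_gene = g`` iff ``source_start >= g.start`` and
    ``source_end <= g.end``; partial overlap yields no truth. Loci must
    not overlap. Idempotent and order-invariant.
    """
    loci = sorted(loci, key=lambda g: g.start)
    for a, b in zip(loci, loci[1:]):
        if a.end >= b.start:
            raise ValueError(f"overlapping loci {a.gene_name!r} and {b.gene_name!r}")
    out = []
    for frag in fragments:
        truth = None
        for g in loci:
            if g.start <= frag.source_start and frag.source_end <= g.end:
                truth = g.gene_name
                break
        out.append(replace(frag, truth_gene=truth))
    return out


def evaluate_calls(report: Report, fragments) -> EvaluationResult:
    """Score one gene's report against truth-labelled fragments.

    ``n_correct`` counts annotated calls whose fragment truth matches the
    report's gene; ``n_false`` counts annotated calls whose fragment has a
    different (or no) truth label. Sensitivity is ``n_correct / n_truth``
    (None when the gene has no truth fragments).
    """
    truth = {}
    for f in fragments:
        truth[f.fragment_id] = f.truth_gene
    n_truth = sum(1 for t in truth.values() if t == report.gene_name)
    n_correct = n_false = 0
    for call in report.annotated:
        if call.fragment_id not in truth:
            raise KeyError(f"unknown fragment id {call.fragment_id!r}")
        if truth[call.fragment_id] == report.gene_name:
            n_correct += 1
        else:
            n_false += 1
    return EvaluationResult(
        gene_name=report.gene_name,
        n_truth=n_truth,
        n_called=len(report.annotated),
        n_correct=n_correct,
        n_false=n_false,
        sensitivity=(n_correct / n_truth) if n_truth > 0 else None,
    )


# ---------------------------------------------------------------------------
# toy world


@dataclass
class ToyWorld:
    """A synthetic genome + curated reference database with known answers."""

    genome: SeqRecord
    loci: list[GeneLocus]
    refdb: ReferenceDB
    gene_specs: list[GeneSpec]
    target_genes: list[str]
    absent_gene: str
    decoy_pair: tuple[str, str] | None
    divergence: dict[str, float]
    high_conservation_gene: str
    low_conservation_gene: str
    family_consensus: dict[str, str] = field(default_factory=dict)

    def locus_of(self, gene_name: str) -> GeneLocus | None:
        for g in self.loci:
            if g.gene_name == gene_name:
                return g
        return None


def _random_protein(rng, length, background) -> str:
    idx = rng.choice(len(PROTEIN_ALPHABET), size=length, p=background)
    return "".join(PROTEIN_ALPHABET[i] for i in idx)


def _mutate(rng, seq: str, rate: float, protect: int = 0, protect_rate: float = 0.02) -> str:
    """Substitute residues at `rate`; the first `protect` positions (the
    conserved shared domain) mutate at `protect_rate` instead."""
    out = list(seq)
    for i in range(len(out)):
        r = protect_rate if i < protect else rate
        if rng.random() < r:
            choices = [c for c in PROTEIN_ALPHABET if c != out[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _reverse_translate(protein: str) -> str:
    return "".join(PREFERRED_CODON[c] for c in protein) + STOP_CODON


def _family_rates(n: int) -> list[float]:
    """Per-family divergence: families 2 and 3 (when present) are the
    designated high- and low-conservation families."""
    base = np.linspace(0.08, 0.22, n)
    rates = list(np.round(base, 3))
    if n > 0:
        rates[0] = 0.10
    if n > 1:
        rates[1] = 0.10
    if n > 2:
        rates[2] = 0.03
    if n > 3:
        rates[3] = 0.30
    return rates


def make_toy_world(
    seed: int,
    n_families: int = 6,
    members_per_family: int = 8,
    domain_library_size: int = 24,
    domains_per_family: int = 4,
    decoy: bool = True,
    spacer_length: int = 8000,
) -> ToyWorld:
    """Build a deterministic synthetic world with planted gene families.

    Each family is a concatenation of ``domains_per_family`` blocks from a
    seeded domain library, diversified into members at a per-family
    substitution rate. With ``decoy=True`` families 0 and 1 share their
    first domain block (kept conserved in both — the ubiquitous-domain
    scenario); family 1 is the decoy paralog and is present in the genome
    but absent from the gene list. The last family is a listed target with
    no genome locus. One member per present family is reverse-translated
    (most-used codons, table 11) into a genome with random intergenic
    spacers; even-indexed genes sit on the plus strand, odd-indexed on the
    minus strand.
    """
    if n_families < 2:
        raise ValueError("need at least 2 families")
    need = n_families * domains_per_family - (1 if decoy else 0)
    if domain_library_size < need:
        raise ValueError(f"domain library too small: need {need}")
    rng = np.random.default_rng([seed, 202])
    background = SubstitutionMatrix.blosum62().background

    library = [
        _random_protein(rng, int(rng.integers(45, 71)), background)
        for _ in range(domain_library_size)
    ]

    # domain assignment: disjoint blocks, except the shared decoy domain
    pool = list(range(domain_library_size))
    assignments: list[list[int]] = []
    for fam in range(n_families):
        if decoy and fam == 1:
            take = [assignments[0][0]] + pool[: domains_per_family - 1]
            pool = pool[domains_per_family - 1 :]
        else:
            take = pool[:domains_per_family]
            pool = pool[domains_per_family:]
        assignments.append(take)

    rates = _family_rates(n_families)
    consensi = ["".join(library[d] for d in doms) for doms in assignments]
    shared_len = len(library[assignments[0][0]]) if decoy else 0

    proteins: list[SeqRecord] = []
    cog_rows: list[tuple[str, str, str]] = []
    members: dict[int, list[str]] = {}
    for fam in range(n_families):
        protect = shared_len if (decoy and fam in (0, 1)) else 0
        members[fam] = []
        for j in range(members_per_family):
            seq = _mutate(rng, consensi[fam], rates[fam], protect=protect)
            pid = f"F{fam}_M{j}"
            proteins.append(SeqRecord(Seq(seq), id=pid, description=""))
            cog_rows.append((pid, f"COG{fam:04d}", f"Species_{fam}_{j}"))
            members[fam].append(seq)
    if n_families >= 3:
        # one fused (multi-COG) protein exercises the fusion-rejection rule
        fused = members[0][1] + members[2][1]
        proteins.append(SeqRecord(Seq(fused), id="FUSED_0_2", description=""))
        cog_rows.append(("FUSED_0_2", "COG0000", "Species_fused"))
        cog_rows.append(("FUSED_0_2", "COG0002", "Species_fused"))
    refdb = build_refdb(proteins, cog_rows)

    absent = n_families - 1
    present = [f for f in range(n_families) if f != absent]
    nt = {"A", "C", "G", "T"}
    parts: list[str] = []
    loci: list[GeneLocus] = []
    pos = 0

    def spacer() -> str:
        arr = rng.integers(0, 4, size=spacer_length)
        return "".join("ACGT"[i] for i in arr)

    for fam in present:
        sp = spacer()
        parts.append(sp)
        pos += len(sp)
        cds = _reverse_translate(members[fam][0])
        strand = "+" if fam % 2 == 0 else "-"
        if strand == "-":
            cds = str(Seq(cds).reverse_complement())
        loci.append(GeneLocus(f"gene{fam}", pos + 1, pos + len(cds), strand))
        parts.append(cds)
        pos += len(cds)
    parts.append(spacer())
    genome = SeqRecord(Seq("".join(parts)), id="toy_genome", description="")

    target_fams = [f for f in range(n_families) if not (decoy and f == 1)]
    gene_specs = [
        GeneSpec(f"gene{f}", f"COG{f:04d}", f"gene{f}_model") for f in target_fams
    ]
    return ToyWorld(
        genome=genome,
        loci=loci,
        refdb=refdb,
        gene_specs=gene_specs,
        target_genes=[f"gene{f}" for f in target_fams if f != absent],
        absent_gene=f"gene{absent}",
        decoy_pair=("gene0", "gene1") if decoy else None,
        divergence={f"gene{f}": rates[f] for f in range(n_families)},
        high_conservation_gene="gene2" if n_families > 2 else "gene0",
        low_conservation_gene="gene3" if n_families > 3 else f"gene{n_families-1}",
        family_consensus={f"gene{f}": consensi[f] for f in range(n_families)},
    )


# ---------------------------------------------------------------------------
# cutoff-sweep baseline (the plain translated-search comparator)


def baseline_best_evalues(
    query: str,
    fragments,
    effective_db_length: float = 1.0e9,
    genetic_code: int = 11,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> dict[str, float]:
    """Best E-value per fragment for a plain six-frame local-alignment
    search against a single protein query (the cutoff-based comparator;
    multiple high-scoring pairs per fragment count once).

    E-values use gapped BLOSUM62 Gumbel constants against the effective
    database length. Fragments with no positive-scoring alignment are
    omitted.
    """
    from Bio.Align import PairwiseAligner, substitution_matrices
    from .translated_search import six_frame_translate

    query = str(query.seq) if hasattr(query, "seq") else str(query)
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend

    import math as _math
    from .reciprocal_check import KA_K, KA_LAMBDA

    out: dict[str, float] = {}
    for frag in fragments:
        seq = frag.sequence if isinstance(frag, Fragment) else str(frag.seq)
        fid = frag.fragment_id if isinstance(frag, Fragment) else frag.id
        best = 0.0
        for fp in six_frame_translate(seq, genetic_code):
            if fp.peptide:
                raw = aligner.score(query, fp.peptide)
                best = max(best, raw)
        if best > 0:
            out[fid] = KA_K * len(query) * effective_db_length * _math.exp(
                -KA_LAMBDA * best
            )
    return out


def cutoff_sweep(
    query: str,
    fragments,
    cutoffs,
    effective_db_length: float = 1.0e9,
    genetic_code: int = 11,
) -> dict[float, int]:
    """Hit counts of the plain cutoff-based search at each expect cutoff.

    ``cutoffs`` must be sorted from permissive to stringent (descending);
    counts are monotone non-increasing along the sweep.
    """
    cutoffs = list(cutoffs)
    if any(a < b for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be sorted descending")
    evalues = baseline_best_evalues(
        query, fragments, effective_db_length, genetic_code
    )
    values = np.array(sorted(evalues.values()))
    return {c: int(np.searchsorted(values, c, side="right")) for c in cutoffs}


# ---------------------------------------------------------------------------
# fragment FASTA round-trip (truth carried in the description line)


def fragments_to_records(fragments) -> list[SeqRecord]:
    out = []
    for f in fragments:
        desc = (
            f"truth={f.truth_gene or 'none'} "
            f"pos={f.source_start}-{f.source_end} strand={f.source_strand}"
        )
        out.append(SeqRecord(Seq(f.sequence), id=f.fragment_id, description=desc))
    return out


def records_to_fragments(records) -> list[Fragment]:
    out = []
    for rec in records:
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split() if "=" in kv
        )
        start, end = fields["pos"].split("-")
        truth = fields["truth"]
        out.append(
            Fragment(
                fragment_id=rec.id,
                sequence=str(rec.seq),
                source_start=int(start),
                source_end=int(end),
                source_strand=fields["strand"],
                truth_gene=None if truth == "none" else truth,
            )
        )
    return out


def write_loci(loci, path) -> None:
    """Write loci as TSV. Coordinates are 1-based inclusive (NOT BED
    half-open), as stated in the file header."""
    with open(path, "w", newline="\n") as fh:
        fh.write("# gene\tstart\tend\tstrand (coordinates 1-based inclusive)\n")
        for g in sorted(loci, key=lambda x: x.start):
            fh.write(f"{g.gene_name}\t{g.start}\t{g.end}\t{g.strand}\n")
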