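"""Map called variants to features and amino-acid consequences, read/write
mutation tables, and compute cross-strain recurrence.

Mutation tables use eight columns — Chr, Pos, Ref, Alt, Zygosity,
Annotation, Syn?, Gene — with the "Syn?" column holding ``syn`` for
synonymous CDS changes, ``X n Y`` for missense (ref residue, 1-based codon
index, alt residue), ``X n *`` for nonsense, ``-Naa`` for frameshifts
(change in protein length), and blank for non-CDS rows.  Indel rows carry an
empty Ref and a ``+SEQ``/``-SEQ`` Alt.

The transcribed per-strain tables for the five evolved clones (E1..E5) ship
with the package and are loadable via :func:`load_published_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import ConfigError, CoordinateError, ParseError
from .filtering import IndelCall, SnpCall
from .genome import (
    BASES,
    GeneModel,
    GeneticCode,
    GenomeSequence,
    STANDARD_CODE,
    extract_cds,
    reverse_complement,
)

TABLE_COLUMNS = ("Chr", "Pos", "Ref", "Alt", "Zygosity", "Annotation", "Syn?", "Gene")

#: Generations of selection for each sequenced evolved clone.
STRAIN_GENERATIONS = {"E1": 460, "E2": 250, "E3": 250, "E4": 301, "E5": 264}


@dataclass(frozen=True)
class AnnotatedVariant:
    chrom: str
    pos: int
    ref: str  # empty for indel rows
    alt: str  # base, or indel string like "+A"
    zygosity_transition: str
    annotation: str  # CDS, intergenic, intron, tRNA, LTR, 5' UTR
    consequence: str  # "", "syn", "X n Y", "X n *", "-Naa"
    gene: str

    @property
    def is_indel(self) -> bool:
        return self.alt.startswith(("+", "-"))

    @property
    def is_cds(self) -> bool:
        return self.annotation == "CDS"

    @property
    def is_synonymous(self) -> bool:
        return self.consequence == "syn"


@dataclass
class MutationTable:
    strain: str
    generations: int
    rows: list[AnnotatedVariant]

    def __post_init__(self) -> None:
        if self.generations <= 0:
            raise ConfigError("generations must be positive")

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# annotation


def _cds_offset(gene: GeneModel, pos: int) -> int:
    """0-based offset of ``pos`` along the coding sequence, in translation
    order (transcription-direction aware)."""
    intervals = sorted(gene.intervals, reverse=gene.strand == "-")
    offset = 0
    for s, e in intervals:
        if s <= pos <= e:
            return offset + (pos - s if gene.strand == "+" else e - pos)
        offset += e - s + 1
    raise CoordinateError(f"{pos} not in CDS of {gene.gene_id}")


def _protein_length(seq: str, code: GeneticCode) -> int:
    """Residues translated before the first stop (or sequence end)."""
    n = 0
    for i in range(0, len(seq) - len(seq) % 3, 3):
        if code.is_stop(seq[i : i + 3]):
            return n
        n += 1
    return n


def _snp_consequence(gene: GeneModel, genome: GenomeSequence, pos: int,
                     alt: str, code: GeneticCode) -> str:
    codons = extract_cds(genome, gene)
    offset = _cds_offset(gene, pos)
    idx, within = divmod(offset, 3)
    ref_codon = codons[idx]
    alt_base = alt if gene.strand == "+" else reverse_complement(alt)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = code.translate(ref_codon)
    alt_aa = code.translate(alt_codon)
    if ref_aa == alt_aa:
        return "syn"
    return f"{ref_aa} {idx + 1} {alt_aa}"


def _indel_consequence(gene: GeneModel, genome: GenomeSequence, pos: int,
                       indel: str, code: GeneticCode) -> str:
    seq = "".join(genome.fetch(gene.chrom, s, e) for s, e in sorted(gene.intervals))
    if gene.strand == "-":
        seq = reverse_complement(seq)
        indel_seq = reverse_complement(indel[1:])
    else:
        indel_seq = indel[1:]
    offset = _cds_offset(gene, pos)
    if indel.startswith("+"):
        mutated = seq[: offset + 1] + indel_seq + seq[offset + 1 :]
    else:
        mutated = seq[: offset + 1] + seq[offset + 1 + len(indel_seq) :]
    if abs(len(mutated) - len(seq)) % 3 == 0:
        return "syn" if mutated == seq else "inframe"
    delta = _protein_length(mutated, code) - _protein_length(seq, code)
    return f"{delta}aa" if delta < 0 else f"+{delta}aa"


def _flanking_genes(genes: list[GeneModel], chrom: str, pos: int) -> str:
    before = after = None
    for g in genes:
        if g.chrom != chrom:
            continue
        start = min(s for s, _ in g.intervals)
        end = max(e for _, e in g.intervals)
        if end < pos and (before is None or end > before[0]):
            before = (end, g.gene_id)
        if start > pos and (after is None or start < after[0]):
            after = (start, g.gene_id)
    names = [x[1] for x in (before, after) if x is not None]
    return "/".join(names)


def annotate_variant(call: SnpCall | IndelCall, genome: GenomeSequence,
                     genes: Iterable[GeneModel],
                     code: GeneticCode = STANDARD_CODE) -> AnnotatedVariant:
    """Attach feature class, gene and amino-acid consequence to a call."""
    genes = list(genes)
    if call.chrom not in genome:
        raise CoordinateError(f"unknown chromosome {call.chrom!r}")
    if isinstance(call, SnpCall):
        ref, alt, zyg = call.ref, call.alt, call.zygosity_transition
    else:
        ref, alt, zyg = "", call.indel_string, ""
    hits = [g for g in genes if g.chrom == call.chrom and g.contains(call.pos)]
    hits.sort(key=lambda g: g.feature_class != "CDS")  # CDS wins overlaps
    if not hits:
        return AnnotatedVariant(call.chrom, call.pos, ref, alt, zyg, "intergenic",
                                "", _flanking_genes(genes, call.chrom, call.pos))
    gene = hits[0]
    if gene.feature_class != "CDS":
        return AnnotatedVariant(call.chrom, call.pos, ref, alt, zyg,
                                gene.feature_class, "", gene.gene_id)
    if isinstance(call, SnpCall):
        if alt not in BASES:
            raise ConfigError(f"invalid alt base {alt!r}")
        cons = _snp_consequence(gene, genome, call.pos, alt, code)
    else:
        cons = _indel_consequence(gene, genome, call.pos, alt, code)
    return AnnotatedVariant(call.chrom, call.pos, ref, alt, zyg, "CDS", cons,
                            gene.gene_id)


# ---------------------------------------------------------------------------
# mutation-table I/O


def parse_mutation_table(path: str | Path, strain: str = "",
                         generations: int = 1) -> MutationTable:
    lines = Path(path).read_text().splitlines()
    rows: list[AnnotatedVariant] = []
    header_seen = False
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if not header_seen:
            if tuple(fields) != TABLE_COLUMNS:
                raise ParseError(f"{path}:{lineno}: bad header {fields!r}")
            header_seen = True
            continue
        if len(fields) != len(TABLE_COLUMNS):
            raise ParseError(
                f"{path}:{lineno}: expected {len(TABLE_COLUMNS)} fields, "
                f"got {len(fields)}")
        chrom, pos_s, ref, alt, zyg, annot, syn, gene = fields
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer position") from exc
        rows.append(AnnotatedVariant(chrom, pos, ref, alt, zyg, annot, syn, gene))
    return MutationTable(strain=strain, generations=generations, rows=rows)


def write_mutation_table(table: MutationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for r in table.rows:
            fh.write("\t".join([r.chrom, str(r.pos), r.ref, r.alt,
                                r.zygosity_transition, r.annotation,
                                r.consequence, r.gene]) + "\n")


def load_published_table(strain: str) -> MutationTable:
    """Load one of the transcribed per-strain mutation tables (E1..E5)."""
    if strain not in STRAIN_GENERATIONS:
        raise ConfigError(f"unknown strain {strain!r}; expected one of E1..E5")
    ref = resources.files("evoscan.data") / f"table{strain}.tsv"
    with resources.as_file(ref) as path:
        return parse_mutation_table(path, strain=strain,
                                    generations=STRAIN_GENERATIONS[strain])


def load_published_tables() -> list[MutationTable]:
    return [load_published_table(s) for s in STRAIN_GENERATIONS]


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class TableSummary:
    strain: str
    generations: int
    n_rows: int
    n_snps: int
    n_indels: int
    n_het_endpoint: int
    n_hom_transition: int
    n_cds_rows: int
    n_cds_snps: int
    n_nonsyn_cds_snps: int


def summarize_table(table: MutationTable) -> TableSummary:
    """Raw row-derived counts (no MNV merging, no forcing to prose counts)."""
    rows = table.rows
    snps = [r for r in rows if not r.is_indel]
    cds = [r for r in rows if r.is_cds]
    cds_snps = [r for r in cds if not r.is_indel]
    return TableSummary(
        strain=table.strain,
        generations=table.generations,
        n_rows=len(rows),
        n_snps=len(snps),
        n_indels=len(rows) - len(snps),
        n_het_endpoint=sum(r.zygosity_transition.endswith("het") for r in rows),
        n_hom_transition=sum(
            r.zygosity_transition.split("->")[-1].startswith("hom") for r in rows
            if r.zygosity_transition),
        n_cds_rows=len(cds),
        n_cds_snps=len(cds_snps),
        n_nonsyn_cds_snps=sum(not r.is_synonymous for r in cds_snps),
    )


def recurrence(tables: Iterable[MutationTable]) -> dict[str, set[str]]:
    """For each gene with a CDS row in any strain, the set of strains hit.

    Intergenic flanking-gene labels are excluded.
    """
    hits: dict[str, set[str]] = {}
    for table in tables:
        for r in table.rows:
            if r.is_cds and r.gene:
                hits.setdefault(r.gene, set()).add(table.strain)
    return hits
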