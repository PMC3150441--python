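"""Genome sequences, gene models, the genetic code, and genome-wide
mutation-consequence probabilities.

Two probabilities summarize how point mutations are expected to behave in a
gene-dense genome: the chance a uniformly random genomic mutation lands in a
coding region (``coding_fraction``), and the chance a random coding mutation
changes the encoded amino acid (``genome_nonsyn_probability``).  The latter is
computed by enumerating, for every sense codon in every CDS, all nine
single-nucleotide mutants and asking which encode a different residue (or a
stop), then averaging that per-codon fraction over all codons.

Coordinates are 1-based inclusive throughout this module; BED-like files on
disk are 0-based half-open and converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .errors import ConfigError, CoordinateError, FrameError, ParseError

BASES = "ACGT"

#: Haploid nuclear genome length of S. cerevisiae S288c (bp), the default L
#: for neutral-mutation expectations; the mitochondrial genome is excluded.
SACCHAROMYCES_NUCLEAR_BP = 12_071_326

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """Uppercase DNA sequences keyed by unique chromosome names."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if len(seq) < 1:
                raise ConfigError(f"chromosome {name!r} is empty")
            if set(seq) - set("ACGTN"):
                raise ConfigError(f"chromosome {name!r} has non-ACGTN characters")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def total_length(self) -> int:
        """Genome size L in bp, summed over chromosomes."""
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence by 1-based inclusive coordinates."""
        if chrom not in self.sequences:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        if start < 1 or end > len(self.sequences[chrom]) or start > end:
            raise CoordinateError(
                f"{chrom}:{start}-{end} outside 1..{len(self.sequences[chrom])}"
            )
        return self.sequences[chrom][start - 1 : end]


FEATURE_CLASSES = ("CDS", "intron", "tRNA", "LTR", "5' UTR", "intergenic")


@dataclass(frozen=True)
class GeneModel:
    """A gene with ordered 1-based inclusive CDS intervals.

    Intervals are listed in transcription order: ascending for ``+`` genes,
    descending for ``-`` genes.  For non-CDS feature classes the intervals
    simply delimit the feature footprint.
    """

    gene_id: str
    chrom: str
    strand: str
    intervals: tuple[tuple[int, int], ...]
    feature_class: str = "CDS"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ConfigError(f"strand must be + or -, got {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ConfigError(f"unknown feature class {self.feature_class!r}")
        if not self.intervals:
            raise ConfigError(f"gene {self.gene_id}: no intervals")
        spans = sorted(self.intervals)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ConfigError(f"gene {self.gene_id}: overlapping intervals")
        for s, e in spans:
            if s < 1 or e < s:
                raise ConfigError(f"gene {self.gene_id}: bad interval {(s, e)}")

    @property
    def span_length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.intervals)


class GeneticCode:
    """A 64-codon translation table; the standard nuclear code by default."""

    def __init__(self, table: Mapping[str, str] | None = None):
        if table is None:
            ncbi = unambiguous_dna_by_id[1]
            table = dict(ncbi.forward_table)
            for stop in ncbi.stop_codons:
                table[stop] = "*"
        table = {c.upper(): aa for c, aa in table.items()}
        if len(table) != 64:
            raise ConfigError(f"genetic code must map 64 codons, got {len(table)}")
        self.table = table
        self.stop_codons = frozenset(c for c, aa in table.items() if aa == "*")
        self.sense_codons = tuple(sorted(set(table) - self.stop_codons))

    def translate(self, codon: str) -> str:
        codon = codon.upper()
        if codon not in self.table:
            raise ConfigError(f"not a valid codon: {codon!r}")
        return self.table[codon]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneticCode":
        """Load a 64-line ``codon<TAB>amino_acid`` table (``*`` for stop)."""
        table: dict[str, str] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                codon, aa = line.split("\t")
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: expected 2 tab-separated fields") from exc
            table[codon.strip().upper()] = aa.strip()
        return cls(table)


STANDARD_CODE = GeneticCode()


@dataclass(frozen=True)
class ConsequenceProbabilities:
    """Genome-wide mutation-consequence summary.

    p_coding
        Probability a uniformly random genomic point mutation lands in a
        coding region (stop codons included in the footprint).
    p_nonsyn
        Probability a random coding mutation changes the encoded amino acid
        (creating a stop counts as a change).
    """

    p_coding: float
    p_nonsyn: float

    def __post_init__(self) -> None:
        for name in ("p_coding", "p_nonsyn"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")


def extract_cds(genome: GenomeSequence, gene: GeneModel) -> list[str]:
    """In-frame codons of a CDS gene, in translation order.

    Minus-strand genes are reverse-complemented before codon splitting.
    """
    parts = [genome.fetch(gene.chrom, s, e) for s, e in sorted(gene.intervals)]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    if len(seq) % 3 != 0:
        raise FrameError(
            f"gene {gene.gene_id}: CDS length {len(seq)} not divisible by 3"
        )
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def codon_nonsyn_fraction(codon: str, code: GeneticCode = STANDARD_CODE) -> float:
    """Fraction of the 9 single-nucleotide mutants of ``codon`` that encode a
    different amino acid or a stop.

    E.g. a codon with a four-fold degenerate wobble base yields 6/9.
    """
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set(BASES):
        raise ConfigError(f"not an unambiguous codon: {codon!r}")
    if code.is_stop(codon):
        raise ConfigError(f"stop codon {codon} encodes no amino acid")
    aa = code.translate(codon)
    changed = 0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if code.translate(mutant) != aa:
                changed += 1
    return changed / 9.0


def genome_nonsyn_probability(
    genome: GenomeSequence,
    genes: Iterable[GeneModel],
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Codon-count-weighted mean of ``codon_nonsyn_fraction`` over all sense
    codons of all CDS genes.

    Stop codons are skipped (they encode no amino acid); codons containing N
    are skipped as untranslatable.  Overlapping genes are counted
    independently, matching a naive per-codon sweep.
    """
    # memoize per distinct codon: only 61 values ever needed
    cache: dict[str, float] = {}
    total = 0.0
    n = 0
    for gene in genes:
        if gene.feature_class != "CDS":
            continue
        for codon in extract_cds(genome, gene):
            if "N" in codon or code.is_stop(codon):
                continue
            if codon not in cache:
                cache[codon] = codon_nonsyn_fraction(codon, code)
            total += cache[codon]
            n += 1
    if n == 0:
        raise ConfigError("no sense codons in any CDS gene")
    return total / n


def coding_fraction(genome: GenomeSequence, genes: Iterable[GeneModel]) -> float:
    """Fraction of the genome covered by the union of CDS intervals
    (stop codons included)."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for gene in genes:
        if gene.feature_class != "CDS":
            continue
        if gene.chrom not in genome:
            raise CoordinateError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom}")
        for s, e in gene.intervals:
            if e > genome.length(gene.chrom):
                raise CoordinateError(f"gene {gene.gene_id}: {s}-{e} out of bounds")
            per_chrom.setdefault(gene.chrom, []).append((s, e))
    covered = 0
    for ivs in per_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e + 1:
                covered += cur_e - cur_s + 1
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s + 1
    return covered / genome.total_length


def consequence_probabilities(
    genome: GenomeSequence,
    genes: Iterable[GeneModel],
    code: GeneticCode = STANDARD_CODE,
) -> ConsequenceProbabilities:
    genes = list(genes)
    return ConsequenceProbabilities(
        p_coding=coding_fraction(genome, genes),
        p_nonsyn=genome_nonsyn_probability(genome, genes, code),
    )


# ---------------------------------------------------------------------------
# on-disk formats


def read_fasta(path: str | Path) -> GenomeSequence:
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"duplicate chromosome name {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """BED-like tab file: chrom, start0, end, gene_id, strand, feature_class.

    On-disk coordinates are 0-based half-open; rows sharing a gene_id are
    collected into one multi-interval model.
    """
    raw: dict[str, dict] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 6:
            raise ParseError(f"{path}:{i}: expected >=6 tab-separated fields")
        chrom, start0, end, gene_id, strand, fclass = fields[:6]
        try:
            s, e = int(start0) + 1, int(end)
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: non-integer coordinates") from exc
        entry = raw.setdefault(
            gene_id, {"chrom": chrom, "strand": strand, "fclass": fclass, "ivs": []}
        )
        if entry["chrom"] != chrom or entry["strand"] != strand:
            raise ParseError(f"{path}:{i}: gene {gene_id} spans chromosomes/strands")
        entry["ivs"].append((s, e))
    genes = []
    for gene_id, entry in raw.items():
        ivs = sorted(entry["ivs"], reverse=entry["strand"] == "-")
        genes.append(
            GeneModel(gene_id, entry["chrom"], entry["strand"], tuple(ivs), entry["fclass"])
        )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for s, e in sorted(g.intervals):
                fh.write(
                    f"{g.chrom}\t{s - 1}\t{e}\t{g.gene_id}\t{g.strand}\t{g.feature_class}\n"
                )
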