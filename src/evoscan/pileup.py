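"""Per-site read counts for an ancestor/evolved strain pair.

The on-disk dialect is a documented simplification of classic pileup text:
one tab-separated line per site, with strand-split base counts::

    chrI	100	A	A+:5	A-:4	T+:3	T-:2	N:0	*:0	+A:2

Fixed fields are chromosome, 1-based position and reference base; the
remaining tokens are ``<base><strand>:<count>`` for read bases (zero counts
may be omitted), ``N:<count>`` for ambiguous calls, ``*:<count>`` for
deletion markers, and ``<indel>:<count>`` for indel observations such as
``+A`` (insertion) or ``-G`` (deletion).  Canonical files (as produced by
:func:`write_pileup`) list nonzero base tokens in A,C,G,T then +,- order,
always carry ``N:`` and ``*:``, and list indel tokens sorted lexically.

In memory a pileup is a :class:`pandas.DataFrame` with one row per site and
integer count columns (``A+`` .. ``T-``, ``N``, ``*``) plus an ``indels``
object column holding ``{indel_string: count}`` dicts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError

BASES = "ACGT"
COUNT_COLUMNS = [f"{b}{s}" for b in BASES for s in "+-"]
_TOKEN_RE = re.compile(r"^([ACGT][+-]|N|\*|[+-][ACGTN]+):(\d+)$")


@dataclass
class SiteCounts:
    """Read counts at one reference position of one strain."""

    chrom: str
    pos: int
    ref: str
    base_counts: dict  # {"A+": n, ..., "T-": n}
    n_ambiguous: int = 0
    n_del_markers: int = 0
    indel_calls: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.base_counts = {c: int(self.base_counts.get(c, 0)) for c in COUNT_COLUMNS}
        bad = [v for v in self.base_counts.values() if v < 0]
        if bad or self.n_ambiguous < 0 or self.n_del_markers < 0:
            raise ConfigError(f"negative count at {self.chrom}:{self.pos}")

    @property
    def depth(self) -> int:
        """Total reads: bases + ambiguous calls + deletion markers."""
        return sum(self.base_counts.values()) + self.n_ambiguous + self.n_del_markers

    @property
    def unambiguous_depth(self) -> int:
        """Reads carrying an unambiguous base call (denominator for SNP
        allele frequencies; N and * are quality signals, not alleles)."""
        return sum(self.base_counts.values())

    def base_support(self, base: str, strand: str | None = None) -> int:
        if strand is not None:
            return self.base_counts[f"{base}{strand}"]
        return self.base_counts[f"{base}+"] + self.base_counts[f"{base}-"]


@dataclass
class PairedSite:
    ancestor: SiteCounts
    evolved: SiteCounts

    def __post_init__(self) -> None:
        a, e = self.ancestor, self.evolved
        if (a.chrom, a.pos) != (e.chrom, e.pos):
            raise ConfigError(
                f"paired sites disagree: {a.chrom}:{a.pos} vs {e.chrom}:{e.pos}"
            )


def allele_frequency(site: SiteCounts, allele: str) -> float:
    """Fraction of reads supporting ``allele`` at this site.

    Base alleles are measured against the unambiguous depth; indel alleles
    (``+A``, ``-G`` strings) against the total depth.
    """
    if allele in BASES:
        denom = site.unambiguous_depth
        num = site.base_support(allele)
    else:
        denom = site.depth
        num = site.indel_calls.get(allele, 0)
    if denom == 0:
        raise ZeroDivisionError(f"no usable reads at {site.chrom}:{site.pos}")
    return num / denom


# ---------------------------------------------------------------------------
# table <-> file


def empty_table() -> pd.DataFrame:
    cols = {"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64),
            "ref": pd.Series(dtype=str)}
    for c in COUNT_COLUMNS + ["N", "*"]:
        cols[c] = pd.Series(dtype=np.int64)
    cols["indels"] = pd.Series(dtype=object)
    return pd.DataFrame(cols)


def site_from_row(row: Mapping) -> SiteCounts:
    return SiteCounts(
        chrom=row["chrom"],
        pos=int(row["pos"]),
        ref=row["ref"],
        base_counts={c: int(row[c]) for c in COUNT_COLUMNS},
        n_ambiguous=int(row["N"]),
        n_del_markers=int(row["*"]),
        indel_calls=dict(row["indels"]) if row["indels"] else {},
    )


def read_pileup(path: str | Path) -> pd.DataFrame:
    """Parse a simplified pileup TSV into a site table.

    Sites must be unique and sorted by position within each chromosome.
    """
    rows = []
    seen_chroms: list[str] = []
    last_pos = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        chrom, pos_s, ref = fields[:3]
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer position {pos_s!r}") from exc
        if chrom in last_pos:
            if seen_chroms[-1] != chrom:
                raise ParseError(f"{path}:{lineno}: chromosome {chrom} not contiguous")
            if pos == last_pos[chrom]:
                raise ParseError(f"{path}:{lineno}: duplicated position {chrom}:{pos}")
            if pos < last_pos[chrom]:
                raise ParseError(f"{path}:{lineno}: unsorted position {chrom}:{pos}")
        else:
            seen_chroms.append(chrom)
        last_pos[chrom] = pos
        counts = dict.fromkeys(COUNT_COLUMNS + ["N", "*"], 0)
        indels: dict[str, int] = {}
        for tok in fields[3:]:
            if not tok:
                continue
            m = _TOKEN_RE.match(tok)
            if not m:
                raise ParseError(f"{path}:{lineno}: bad count token {tok!r}")
            key, n = m.group(1), int(m.group(2))
            if key in counts:
                counts[key] = n
            else:
                indels[key] = n
        rows.append({"chrom": chrom, "pos": pos, "ref": ref.upper(),
                     **counts, "indels": indels or None})
    if not rows:
        return empty_table()
    df = pd.DataFrame(rows)
    for c in ["pos"] + COUNT_COLUMNS + ["N", "*"]:
        df[c] = df[c].astype(np.int64)
    return df


def write_pileup(table: pd.DataFrame, path: str | Path) -> None:
    """Serialize a site table in canonical form (see module docstring)."""
    cols = {c: table[c].to_numpy() for c in table.columns}
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\tcounts...\n")
        for k in range(len(table)):
            toks = [f"{c}:{cols[c][k]}" for c in COUNT_COLUMNS if cols[c][k] > 0]
            toks.append(f"N:{cols['N'][k]}")
            toks.append(f"*:{cols['*'][k]}")
            indels = cols["indels"][k]
            if indels:
                toks.extend(f"{s}:{v}" for s, v in sorted(indels.items()))
            fh.write(f"{cols['chrom'][k]}\t{cols['pos'][k]}\t{cols['ref'][k]}\t"
                     + "\t".join(toks) + "\n")


def import_classic_pileup(path: str | Path) -> pd.DataFrame:
    """Convert samtools-style pileup text (chrom, pos, ref, depth, read
    bases, quals) to a site table.

    Mapping-quality carets (``^x``), end markers (``$``) and the quality
    column are normalized away; ``.``/``,`` count toward the reference base
    on + and - strands, letters toward their base, ``*`` as a deletion
    marker, and ``+n<seq>``/``-n<seq>`` runs as indel observations.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 5:
            raise ParseError(f"{path}:{lineno}: expected >=5 pileup fields")
        chrom, pos_s, ref, _depth, bases = fields[:5]
        ref = ref.upper()
        counts = dict.fromkeys(COUNT_COLUMNS + ["N", "*"], 0)
        indels: dict[str, int] = {}
        i = 0
        while i < len(bases):
            ch = bases[i]
            if ch == "^":
                i += 2
                continue
            if ch == "$":
                i += 1
                continue
            if ch in "+-":
                m = re.match(r"[+-](\d+)", bases[i:])
                if not m:
                    raise ParseError(f"{path}:{lineno}: bad indel run at col {i}")
                n = int(m.group(1))
                seq = bases[i + 1 + len(m.group(1)) : i + 1 + len(m.group(1)) + n]
                key = ch + seq.upper()
                indels[key] = indels.get(key, 0) + 1
                i += 1 + len(m.group(1)) + n
                continue
            if ch == ".":
                counts[f"{ref}+"] += 1
            elif ch == ",":
                counts[f"{ref}-"] += 1
            elif ch.upper() in BASES:
                strand = "+" if ch.isupper() else "-"
                counts[f"{ch.upper()}{strand}"] += 1
            elif ch.upper() == "N":
                counts["N"] += 1
            elif ch == "*":
                counts["*"] += 1
            else:
                raise ParseError(f"{path}:{lineno}: unknown pileup char {ch!r}")
            i += 1
        rows.append({"chrom": chrom, "pos": int(pos_s), "ref": ref,
                     **counts, "indels": indels or None})
    if not rows:
        return empty_table()
    df = pd.DataFrame(rows)
    for c in ["pos"] + COUNT_COLUMNS + ["N", "*"]:
        df[c] = df[c].astype(np.int64)
    return df
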