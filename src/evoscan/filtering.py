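"""Ancestor-vs-evolved SNP and indel filtering heuristics.

A site yields a SNP call for an alt base when either rule holds:

* rule A (new heterozygous allele): alt frequency >= 30% in the evolved
  strain and <= 10% in the ancestor;
* rule B (move to homozygosity): alt frequency >= 80% in the evolved strain
  and < 80% in the ancestor.

Additional per-site heuristics: a confirming alt read on both strands in the
evolved strain, at least 5 reads covering the position in both strains, and
no more than one ambiguous ("N") or deletion ("*") call per strain.

Indels require a 30-point allele-frequency difference between strains, raw
coverage of at least 10x in both, and — when more than two distinct indel
strings are seen at a position — that the two most common account for at
least 80% of covering reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, PairingError
from .pileup import (
    BASES,
    COUNT_COLUMNS,
    PairedSite,
    SiteCounts,
    allele_frequency,
    site_from_row,
)

log = logging.getLogger(__name__)

ZYGOSITY_LABELS = {
    "hom_ref": "hom (Ref)",
    "het": "het",
    "hom_alt": "hom (Alt)",
    "ambiguous": "ambiguous",
}


@dataclass(frozen=True)
class FilterParams:
    min_af_evo_het: float = 0.30
    max_af_anc: float = 0.10
    min_af_evo_hom: float = 0.80
    max_af_anc_hom: float = 0.80  # exclusive bound
    min_depth_snp: int = 5
    max_ambiguous: int = 1
    min_depth_indel: int = 10
    min_indel_delta: float = 0.30
    top2_indel_fraction: float = 0.80

    def __post_init__(self) -> None:
        for name in ("min_af_evo_het", "max_af_anc", "min_af_evo_hom",
                     "max_af_anc_hom", "min_indel_delta", "top2_indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.min_depth_snp < 1 or self.min_depth_indel < 1:
            raise ConfigError("depth thresholds must be positive integers")
        if self.max_ambiguous < 0:
            raise ConfigError("max_ambiguous must be >= 0")


@dataclass(frozen=True)
class SnpCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    af_anc: float
    af_evo: float
    zyg_anc: str
    zyg_evo: str
    rule: str  # "A_new_het" or "B_loss_of_het"

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ConfigError("alt equals ref")

    @property
    def zygosity_transition(self) -> str:
        return f"{ZYGOSITY_LABELS[self.zyg_anc]}->{ZYGOSITY_LABELS[self.zyg_evo]}"


@dataclass(frozen=True)
class IndelCall:
    chrom: str
    pos: int
    indel_string: str
    af_anc: float
    af_evo: float

    @property
    def delta_af(self) -> float:
        return self.af_evo - self.af_anc


def classify_zygosity(af: float, params: FilterParams = FilterParams()) -> str:
    """Diploid allelic state from an alt-allele frequency.

    The thresholds reuse the filter constants, leaving (0.10, 0.30) as an
    ambiguous gap.
    """
    if not 0.0 <= af <= 1.0:
        raise ConfigError(f"allele frequency {af} outside [0,1]")
    if af <= params.max_af_anc:
        return "hom_ref"
    if af >= params.min_af_evo_hom:
        return "hom_alt"
    if af >= params.min_af_evo_het:
        return "het"
    return "ambiguous"


def _site_passes_quality(site: SiteCounts, min_depth: int, max_ambiguous: int) -> bool:
    return (site.depth >= min_depth
            and site.n_ambiguous + site.n_del_markers <= max_ambiguous)


def snp_filter(site: PairedSite, alt: str,
               params: FilterParams = FilterParams()) -> SnpCall | None:
    """Apply the SNP rules to one alt base at one paired site.

    Returns a call or None.  Rule B is recorded when both rules hold
    (homozygosity is the stronger claim).
    """
    anc, evo = site.ancestor, site.evolved
    if alt not in BASES or alt == evo.ref:
        raise ConfigError(f"invalid alt base {alt!r} at {evo.chrom}:{evo.pos}")
    for strain, s in (("ancestor", anc), ("evolved", evo)):
        if not _site_passes_quality(s, params.min_depth_snp, params.max_ambiguous):
            log.debug("no-call %s:%d %s: %s fails depth/ambiguity", evo.chrom,
                      evo.pos, alt, strain)
            return None
    if anc.unambiguous_depth == 0 or evo.unambiguous_depth == 0:
        log.debug("no-call %s:%d %s: undefined frequency", evo.chrom, evo.pos, alt)
        return None
    af_anc = allele_frequency(anc, alt)
    af_evo = allele_frequency(evo, alt)
    rule_a = af_evo >= params.min_af_evo_het and af_anc <= params.max_af_anc
    rule_b = af_evo >= params.min_af_evo_hom and af_anc < params.max_af_anc_hom
    if not (rule_a or rule_b):
        return None
    # confirming read on both strands in the strain asserting the new allele
    if evo.base_support(alt, "+") < 1 or evo.base_support(alt, "-") < 1:
        log.debug("no-call %s:%d %s: no strand confirmation", evo.chrom, evo.pos, alt)
        return None
    return SnpCall(
        chrom=evo.chrom, pos=evo.pos, ref=evo.ref, alt=alt,
        af_anc=af_anc, af_evo=af_evo,
        zyg_anc=classify_zygosity(af_anc, params),
        zyg_evo=classify_zygosity(af_evo, params),
        rule="B_loss_of_het" if rule_b else "A_new_het",
    )


def indel_filter(site: PairedSite,
                 params: FilterParams = FilterParams()) -> list[IndelCall]:
    """Apply the indel rules to every indel string seen at a paired site."""
    anc, evo = site.ancestor, site.evolved
    if anc.depth < params.min_depth_indel or evo.depth < params.min_depth_indel:
        return []
    strings = sorted(set(anc.indel_calls) | set(evo.indel_calls))
    if not strings:
        return []
    if len(strings) > 2:
        pooled = {s: anc.indel_calls.get(s, 0) + evo.indel_calls.get(s, 0)
                  for s in strings}
        top2 = sum(sorted(pooled.values(), reverse=True)[:2])
        if top2 < params.top2_indel_fraction * (anc.depth + evo.depth):
            log.debug("no-call %s:%d indels: top-2 rule fails", evo.chrom, evo.pos)
            return []
    calls = []
    for s in strings:
        af_anc = allele_frequency(anc, s)
        af_evo = allele_frequency(evo, s)
        if abs(af_evo - af_anc) >= params.min_indel_delta:
            calls.append(IndelCall(evo.chrom, evo.pos, s, af_anc, af_evo))
    return calls


# ---------------------------------------------------------------------------
# whole-pileup scan (vectorized over the site table)


def _vector_zygosity(af: np.ndarray, params: FilterParams) -> np.ndarray:
    out = np.full(af.shape, "ambiguous", dtype=object)
    out[af <= params.max_af_anc] = "hom_ref"
    out[af >= params.min_af_evo_hom] = "hom_alt"
    out[(af >= params.min_af_evo_het) & (af < params.min_af_evo_hom)] = "het"
    return out


def scan_pair(ancestor: pd.DataFrame, evolved: pd.DataFrame,
              params: FilterParams = FilterParams()) -> list[SnpCall | IndelCall]:
    """Apply the SNP filter at every site for every alt base with nonzero
    evolved support, and the indel filter at every site with indel evidence.

    The two pileups must cover identical coordinates.  Output is sorted by
    (chromosome appearance order, position, alt).
    """
    if len(ancestor) != len(evolved):
        raise PairingError(
            f"pileups differ in length: {len(ancestor)} vs {len(evolved)}")
    if len(ancestor) == 0:
        return []
    if (not np.array_equal(ancestor["chrom"].values, evolved["chrom"].values)
            or not np.array_equal(ancestor["pos"].values, evolved["pos"].values)):
        raise PairingError("pileups cover different coordinates")
    if not np.array_equal(ancestor["ref"].values, evolved["ref"].values):
        raise PairingError("pileups disagree on reference bases")

    ac = {c: ancestor[c].to_numpy() for c in COUNT_COLUMNS + ["N", "*"]}
    ec = {c: evolved[c].to_numpy() for c in COUNT_COLUMNS + ["N", "*"]}
    a_unamb = sum(ac[c] for c in COUNT_COLUMNS)
    e_unamb = sum(ec[c] for c in COUNT_COLUMNS)
    a_depth = a_unamb + ac["N"] + ac["*"]
    e_depth = e_unamb + ec["N"] + ec["*"]
    quality = ((a_depth >= params.min_depth_snp) & (e_depth >= params.min_depth_snp)
               & (ac["N"] + ac["*"] <= params.max_ambiguous)
               & (ec["N"] + ec["*"] <= params.max_ambiguous)
               & (a_unamb > 0) & (e_unamb > 0))
    ref = ancestor["ref"].to_numpy()
    chrom = ancestor["chrom"].to_numpy()
    pos = ancestor["pos"].to_numpy()

    calls: list[SnpCall | IndelCall] = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for alt in BASES:
            a_sup = ac[f"{alt}+"] + ac[f"{alt}-"]
            e_sup = ec[f"{alt}+"] + ec[f"{alt}-"]
            af_anc = np.where(a_unamb > 0, a_sup / np.maximum(a_unamb, 1), np.nan)
            af_evo = np.where(e_unamb > 0, e_sup / np.maximum(e_unamb, 1), np.nan)
            rule_a = (af_evo >= params.min_af_evo_het) & (af_anc <= params.max_af_anc)
            rule_b = (af_evo >= params.min_af_evo_hom) & (af_anc < params.max_af_anc_hom)
            passing = (quality & (ref != alt) & (e_sup > 0) & (rule_a | rule_b)
                       & (ec[f"{alt}+"] >= 1) & (ec[f"{alt}-"] >= 1))
            for i in np.flatnonzero(passing):
                zyg_a = classify_zygosity(float(af_anc[i]), params)
                zyg_e = classify_zygosity(float(af_evo[i]), params)
                calls.append(SnpCall(
                    chrom=str(chrom[i]), pos=int(pos[i]), ref=str(ref[i]), alt=alt,
                    af_anc=float(af_anc[i]), af_evo=float(af_evo[i]),
                    zyg_anc=zyg_a, zyg_evo=zyg_e,
                    rule="B_loss_of_het" if rule_b[i] else "A_new_het",
                ))

    a_ind = ancestor["indels"].to_numpy()
    e_ind = evolved["indels"].to_numpy()
    has_indel = np.array([bool(a) or bool(e) for a, e in zip(a_ind, e_ind)])
    for i in np.flatnonzero(has_indel):
        pair = PairedSite(site_from_row(ancestor.iloc[i]),
                          site_from_row(evolved.iloc[i]))
        calls.extend(indel_filter(pair, params))

    order = {c: k for k, c in enumerate(dict.fromkeys(chrom))}
    calls.sort(key=lambda c: (order[c.chrom], c.pos,
                              getattr(c, "alt", getattr(c, "indel_string", ""))))
    return calls


def calls_to_frame(calls: list[SnpCall | IndelCall]) -> pd.DataFrame:
    """Tabulate calls with the mutation-table column convention."""
    rows = []
    for c in calls:
        if isinstance(c, SnpCall):
            rows.append({"Chr": c.chrom, "Pos": c.pos, "Ref": c.ref, "Alt": c.alt,
                         "Zygosity": c.zygosity_transition, "af_anc": c.af_anc,
                         "af_evo": c.af_evo, "rule": c.rule})
        else:
            rows.append({"Chr": c.chrom, "Pos": c.pos, "Ref": "", "Alt": c.indel_string,
                         "Zygosity": "", "af_anc": c.af_anc, "af_evo": c.af_evo,
                         "rule": "indel_delta_af"})
    return pd.DataFrame(rows, columns=["Chr", "Pos", "Ref", "Alt", "Zygosity",
                                       "af_anc", "af_evo", "rule"])
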