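"""Synthetic inputs for every pipeline stage.

Each generator emulates the statistical structure its consumer assumes:
diploid variants at ~50%/100% allele frequency under binomial read sampling
with a uniform sequencing-error rate; planted CNV segments on Poisson
coverage tracks binned at 1 kb; exponential ln-ratio competition dynamics
with 50,000-cell count sampling; logistic growth curves; and Ct values
encoding locus copy number.

Every generator is a pure function of (config, seed).  Each draws from its
own stream, derived from the scenario seed and a CRC32 hash of the generator
name, so adding one generator never perturbs another's output.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .fitness import CompetitionSample, CompetitionSeries, QpcrRecord
from .genome import GeneModel, GenomeSequence, STANDARD_CODE, write_fasta, write_gene_models
from .pileup import COUNT_COLUMNS, write_pileup

BASES = "ACGT"


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class PlantedVariant:
    chrom: str
    pos: int  # 1-based
    alt: str  # base, or indel string like "+A"
    true_af: float  # 0.5 (het) or 1.0 (hom) for diploid states
    kind: str = "snp"  # "snp" or "indel"

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_af <= 1.0:
            raise ConfigError(f"true_af {self.true_af} outside [0,1]")


@dataclass(frozen=True)
class PlantedCnv:
    chrom: str
    start_bin: int
    end_bin: int  # inclusive
    log2_shift: float


@dataclass
class ScenarioConfig:
    """One bundle of defaults describing a full synthetic study."""

    seed: int = 0
    genome_length: int = 100_000
    n_genes: int = 30
    coding_fraction: float = 0.72
    depth_mean: float = 50.0
    error_rate: float = 0.005
    ambiguous_rate: float = 0.001
    del_marker_rate: float = 0.001
    planted_variants: list[PlantedVariant] = field(default_factory=list)
    # coverage / CNV
    n_coverage_bins: int = 120
    bin_width: int = 1000
    planted_cnvs: list[PlantedCnv] = field(default_factory=list)
    # competition (chemostat defaults: 400 mL working volume, D = 0.17 h^-1)
    competition_s: float = 0.28
    competition_p0: float = 0.5
    n_cells: int = 50_000
    sample_generations: tuple = (0, 3, 6, 9, 12, 15, 18, 20)
    culture_volume_ml: float = 400.0
    dilution_rate_per_h: float = 0.17
    # growth
    growth_mu: float = 0.40
    growth_od0: float = 0.05
    growth_capacity: float = 2.0
    growth_hours: float = 24.0
    growth_dt_h: float = 0.25
    # qPCR
    true_copy_numbers: tuple = (1.0, 2.0, 3.0)
    ct_noise_sd: float = 0.0
    ct0: float = 20.0


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: ScenarioConfig, chrom: str = "chrI"
                    ) -> tuple[GenomeSequence, list[GeneModel]]:
    """Random genome with non-overlapping ORFs (ATG .. stop, no internal
    stops) packed to approximate the requested coding fraction."""
    rng = _rng(config.seed, "genome")
    L, n_genes = config.genome_length, config.n_genes
    coding_bp = int(round(config.coding_fraction * L))
    if n_genes > 0:
        codons_total = max(coding_bp // 3, 2 * n_genes)
        base, extra = divmod(codons_total, n_genes)
        gene_codons = [base + (1 if k < extra else 0) for k in range(n_genes)]
        if sum(3 * c for c in gene_codons) + n_genes > L:
            raise ConfigError("cannot pack requested genes into genome_length")
    else:
        gene_codons = []

    sense = [c for c in STANDARD_CODE.sense_codons if c != "ATG"]
    stops = sorted(STANDARD_CODE.stop_codons)
    intergenic_bp = L - sum(3 * c for c in gene_codons)
    # spread intergenic sequence into n_genes + 1 gaps (each >= 1 bp)
    n_gaps = n_genes + 1
    gaps = np.full(n_gaps, 1)
    remaining = intergenic_bp - n_gaps
    if remaining < 0:
        raise ConfigError("no room for intergenic gaps")
    extra_alloc = rng.multinomial(remaining, np.full(n_gaps, 1.0 / n_gaps))
    gaps = gaps + extra_alloc

    parts: list[str] = []
    genes: list[GeneModel] = []
    cursor = 0
    for k in range(n_genes):
        gap = "".join(rng.choice(list(BASES), size=gaps[k]))
        parts.append(gap)
        cursor += len(gap)
        n_cod = gene_codons[k]
        body = ["ATG"] + list(rng.choice(sense, size=max(n_cod - 2, 0)))
        body.append(str(rng.choice(stops)))
        cds = "".join(body)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            from .genome import reverse_complement
            placed = reverse_complement(cds)
        else:
            placed = cds
        start = cursor + 1
        end = cursor + len(placed)
        parts.append(placed)
        cursor = end
        genes.append(GeneModel(f"g{k + 1:04d}", chrom, strand,
                               ((start, end),), "CDS"))
    parts.append("".join(rng.choice(list(BASES), size=gaps[-1])))
    seq = "".join(parts)
    return GenomeSequence({chrom: seq}), genes


# ---------------------------------------------------------------------------
# pileups


def _strand_split(rng, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fwd = rng.binomial(counts, 0.5)
    return fwd, counts - fwd


def _simulate_strain(rng, genome: GenomeSequence,
                     config: ScenarioConfig,
                     variants: dict[tuple[str, int], PlantedVariant]
                     ) -> pd.DataFrame:
    frames = []
    for chrom, seq in genome.sequences.items():
        n = len(seq)
        refs = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
        depth = rng.poisson(config.depth_mean, n)
        # per-read categories: error to one of 3 alts, N, *, else true allele
        p_err = config.error_rate / 3.0
        pvals = np.array([p_err, p_err, p_err,
                          config.ambiguous_rate, config.del_marker_rate])
        pvals = np.append(pvals, 1.0 - pvals.sum())
        draws = rng.multinomial(depth, pvals)  # (n, 6)
        cols = {c: np.zeros(n, dtype=np.int64) for c in COUNT_COLUMNS + ["N", "*"]}
        cols["N"] = draws[:, 3]
        cols["*"] = draws[:, 4]
        true_reads = draws[:, 5]

        # planted alt reads come out of the true-allele reads
        alt_reads = np.zeros(n, dtype=np.int64)
        alt_base = np.full(n, "", dtype="U1")
        indels_col = np.full(n, None, dtype=object)
        for (vchrom, pos), pv in variants.items():
            if vchrom != chrom:
                continue
            i = pos - 1
            if pv.kind == "snp":
                alt_reads[i] = rng.binomial(true_reads[i], pv.true_af)
                alt_base[i] = pv.alt
            else:
                k = rng.binomial(true_reads[i], pv.true_af)
                if k:
                    indels_col[i] = {pv.alt: int(k)}
        ref_reads = true_reads - alt_reads

        # scatter error reads over the three non-ref bases, split strands
        base_idx = {b: k for k, b in enumerate(BASES)}
        ref_codes = np.array([base_idx.get(r, 0) for r in refs])
        err_choice = np.stack([draws[:, 0], draws[:, 1], draws[:, 2]], axis=1)
        for b in BASES:
            code = base_idx[b]
            total = np.zeros(n, dtype=np.int64)
            total += np.where(ref_codes == code, ref_reads, 0)
            # error slot k maps to the k-th non-ref base in ACGT order
            others = np.array([[c for c in range(4) if c != rc][k]
                               for rc in range(4) for k in range(3)]
                              ).reshape(4, 3)
            for k in range(3):
                total += np.where(others[ref_codes, k] == code, err_choice[:, k], 0)
            total += np.where(alt_base == b, alt_reads, 0)
            fwd, rev = _strand_split(rng, total)
            cols[f"{b}+"] += fwd
            cols[f"{b}-"] += rev

        frame = pd.DataFrame({
            "chrom": chrom, "pos": np.arange(1, n + 1), "ref": refs, **cols,
            "indels": indels_col})
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    for c in ["pos"] + COUNT_COLUMNS + ["N", "*"]:
        out[c] = out[c].astype(np.int64)
    return out


def simulate_pileup_pair(genome: GenomeSequence, config: ScenarioConfig
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ancestor and evolved site tables; planted variants appear only in the
    evolved strain."""
    for pv in config.planted_variants:
        if pv.chrom not in genome or not 1 <= pv.pos <= genome.length(pv.chrom):
            raise ConfigError(f"planted variant outside genome: {pv}")
        if pv.kind == "snp" and pv.alt == genome.fetch(pv.chrom, pv.pos, pv.pos):
            raise ConfigError(f"planted alt equals reference at {pv.chrom}:{pv.pos}")
    anc = _simulate_strain(_rng(config.seed, "pileup_ancestor"), genome, config, {})
    planted = {(pv.chrom, pv.pos): pv for pv in config.planted_variants}
    evo = _simulate_strain(_rng(config.seed, "pileup_evolved"), genome, config,
                           planted)
    return anc, evo


# ---------------------------------------------------------------------------
# coverage


def simulate_coverage_pair(config: ScenarioConfig, chrom: str = "chrI"
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binned ancestor/evolved coverage with planted log2 shifts.

    Each bin value is the mean per-base depth over ``bin_width`` bases,
    emulating raw per-base Poisson coverage averaged into bins: the bin
    total is drawn Poisson(depth_mean * bin_width) and divided by the
    width, so the log2-ratio noise matches what averaged real coverage
    shows at that depth.
    """
    rng = _rng(config.seed, "coverage")
    n = config.n_coverage_bins
    shifts = np.zeros(n)
    occupied = np.zeros(n, dtype=bool)
    for cnv in config.planted_cnvs:
        if cnv.chrom != chrom:
            continue
        if not (0 <= cnv.start_bin <= cnv.end_bin < n):
            raise ConfigError(f"planted CNV outside track: {cnv}")
        span = slice(cnv.start_bin, cnv.end_bin + 1)
        if occupied[span].any():
            raise ConfigError("overlapping planted CNV segments")
        occupied[span] = True
        shifts[span] = cnv.log2_shift
    w = config.bin_width
    anc_depth = rng.poisson(config.depth_mean * w, n) / w
    evo_depth = rng.poisson(config.depth_mean * w * 2.0 ** shifts, n) / w
    start0 = np.arange(n) * config.bin_width
    end = start0 + config.bin_width
    anc = pd.DataFrame({"chrom": chrom, "start0": start0, "end": end,
                        "value": anc_depth})
    evo = pd.DataFrame({"chrom": chrom, "start0": start0, "end": end,
                        "value": evo_depth})
    return evo, anc


# ---------------------------------------------------------------------------
# competition, growth, qPCR


def expected_test_fraction(s: float, g: np.ndarray, p0: float) -> np.ndarray:
    """Logistic frequency trajectory implied by ln-ratio slope s."""
    w = p0 * np.exp(s * np.asarray(g, float))
    return w / (w + (1.0 - p0))


def simulate_competition(config: ScenarioConfig, strain: str = "sim",
                         environment: str = "chemostat") -> CompetitionSeries:
    rng = _rng(config.seed, "competition")
    if not 0.0 < config.competition_p0 < 1.0:
        raise ConfigError("competition_p0 must be in (0,1)")
    g = np.asarray(config.sample_generations, float)
    frac = expected_test_fraction(config.competition_s, g, config.competition_p0)
    counts = rng.binomial(config.n_cells, frac)
    ln2 = np.log(2)
    samples = []
    for gi, ci in zip(g, counts):
        samples.append(CompetitionSample(
            time_h=float(gi * ln2 / config.dilution_rate_per_h),
            count_test=int(ci),
            count_ref=int(config.n_cells - ci),
            effluent_volume_ml=float(gi * config.culture_volume_ml * ln2),
        ))
    return CompetitionSeries(strain=strain, environment=environment,
                             mode="chemostat", samples=samples,
                             culture_volume_ml=config.culture_volume_ml)


def simulate_growth_curve(config: ScenarioConfig
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free logistic OD trajectory with intrinsic rate growth_mu."""
    if config.growth_mu <= 0 or config.growth_od0 <= 0:
        raise ConfigError("growth parameters must be positive")
    t = np.arange(0.0, config.growth_hours + 1e-9, config.growth_dt_h)
    k, od0, mu = config.growth_capacity, config.growth_od0, config.growth_mu
    od = k * od0 * np.exp(mu * t) / (k + od0 * (np.exp(mu * t) - 1.0))
    return t, od


def simulate_qpcr(config: ScenarioConfig) -> list[QpcrRecord]:
    """One record per true copy number; Ct(target) = ct0 - log2(cn) + noise,
    Ct(control) = ct0.  The first record should be the calibrator (cn=1)."""
    rng = _rng(config.seed, "qpcr")
    records = []
    for k, cn in enumerate(config.true_copy_numbers):
        noise = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
        records.append(QpcrRecord(
            sample=f"s{k + 1}",
            ct_target=config.ct0 - np.log2(cn) + noise,
            ct_control=config.ct0))
    return records


# ---------------------------------------------------------------------------
# whole-scenario writer


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """The default study conditions: 20 planted het SNPs at depth 50 and
    0.5% error, one +1.0 log2 CNV over 50 of 120 bins, s = 0.28 with
    50,000-cell sampling, a 0.40 h^-1 logistic growth curve, and copy
    numbers 1/2/3 at zero Ct noise."""
    cfg = ScenarioConfig(seed=seed)
    rng = _rng(seed, "scenario_positions")
    positions = np.sort(rng.choice(
        np.arange(1, cfg.genome_length + 1), size=20, replace=False))
    genome, _ = simulate_genome(cfg)
    variants = []
    for pos in positions:
        ref = genome.fetch("chrI", int(pos), int(pos))
        alt = str(rng.choice([b for b in BASES if b != ref]))
        variants.append(PlantedVariant("chrI", int(pos), alt, 0.5, "snp"))
    cfg.planted_variants = variants
    cfg.planted_cnvs = [PlantedCnv("chrI", 40, 89, 1.0)]
    return cfg


def write_scenario(config: ScenarioConfig, outdir: str | Path) -> dict:
    """Write all synthetic inputs plus a truth.json manifest; returns the
    manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = simulate_genome(config)
    write_fasta(genome, outdir / "genome.fasta")
    write_gene_models(genes, outdir / "genes.tsv")
    anc, evo = simulate_pileup_pair(genome, config)
    write_pileup(anc, outdir / "ancestor.pileup.tsv")
    write_pileup(evo, outdir / "evolved.pileup.tsv")
    evo_cov, anc_cov = simulate_coverage_pair(config)
    from .cnv import write_bedgraph
    write_bedgraph(evo_cov, outdir / "evolved.bedgraph")
    write_bedgraph(anc_cov, outdir / "ancestor.bedgraph")
    series = simulate_competition(config)
    rows = [(s.time_h, s.effluent_volume_ml, s.count_test, s.count_ref)
            for s in series.samples]
    pd.DataFrame(rows, columns=["time_h", "effluent_volume_ml", "count_test",
                                "count_ref"]).to_csv(
        outdir / "competition.tsv", sep="\t", index=False)
    t, od = simulate_growth_curve(config)
    pd.DataFrame({"time_h": t, "od": od}).to_csv(
        outdir / "growth.tsv", sep="\t", index=False)
    records = simulate_qpcr(config)
    pd.DataFrame([(r.sample, r.ct_target, r.ct_control) for r in records],
                 columns=["sample", "ct_target", "ct_control"]).to_csv(
        outdir / "qpcr.tsv", sep="\t", index=False)
    manifest = {
        "seed": config.seed,
        "planted_variants": [asdict(v) for v in config.planted_variants],
        "planted_cnvs": [asdict(c) for c in config.planted_cnvs],
        "competition_s": config.competition_s,
        "growth_mu": config.growth_mu,
        "true_copy_numbers": list(config.true_copy_numbers),
    }
    (outdir / "truth.json").write_text(json.dumps(manifest, indent=2))
    return manifest
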