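"""Competition-assay fitness estimation, batch growth rates, and relative
copy number by the ddCt method.

The per-generation competition (selection) coefficient ``s`` is the OLS
slope of ``ln(test/reference counts)`` against cumulative generations over a
two-strain competition time course.  Generations are counted from chemostat
effluent turnover (``g = V_effluent / V_culture / ln 2``) or from serial
transfers (``g = transfers * log2(dilution factor)``).  Per-strain estimates
are averaged over replicates and normalized so the ancestor equals 1 within
each environment; differences between replicate groups are tested with a
two-tailed Welch t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigError, EstimationError


@dataclass(frozen=True)
class CompetitionSample:
    time_h: float
    count_test: int
    count_ref: int
    effluent_volume_ml: float | None = None  # chemostat mode, cumulative
    transfer_index: int | None = None  # serial mode

    def __post_init__(self) -> None:
        if self.count_test < 0 or self.count_ref < 0:
            raise ConfigError("negative cell counts")
        if self.count_test + self.count_ref == 0:
            raise ConfigError("empty sample (no cells counted)")


@dataclass
class CompetitionSeries:
    strain: str
    environment: str
    mode: str  # "chemostat" or "serial"
    samples: list[CompetitionSample]
    culture_volume_ml: float | None = None  # chemostat
    dilution_factor: float | None = None  # serial

    def __post_init__(self) -> None:
        if self.mode not in ("chemostat", "serial"):
            raise ConfigError(f"unknown competition mode {self.mode!r}")
        if self.mode == "chemostat" and not self.culture_volume_ml:
            raise ConfigError("chemostat series needs culture_volume_ml")
        if self.mode == "serial" and not self.dilution_factor:
            raise ConfigError("serial series needs dilution_factor")
        times = [s.time_h for s in self.samples]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ConfigError("sample times must be non-decreasing")


@dataclass(frozen=True)
class FitnessEstimate:
    s: float
    se: float
    r2: float
    n: int


@dataclass(frozen=True)
class QpcrRecord:
    sample: str
    ct_target: float
    ct_control: float

    def __post_init__(self) -> None:
        if self.ct_target <= 0 or self.ct_control <= 0:
            raise ConfigError("Ct values must be positive")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_control


def generations(sample: CompetitionSample, series: CompetitionSeries) -> float:
    """Cumulative generations elapsed at a sampling point.

    Chemostat: volume turnovers / ln 2 (one turnover dilutes e-fold).
    Serial: transfers * log2(dilution factor).
    """
    if series.mode == "chemostat":
        if sample.effluent_volume_ml is None:
            raise ConfigError("chemostat sample lacks effluent volume")
        if sample.effluent_volume_ml < 0 or series.culture_volume_ml <= 0:
            raise ConfigError("volumes must be non-negative / positive")
        return sample.effluent_volume_ml / series.culture_volume_ml / math.log(2)
    if sample.transfer_index is None:
        raise ConfigError("serial sample lacks transfer index")
    return sample.transfer_index * math.log2(series.dilution_factor)


def generations_from_dilution_rate(dilution_rate_per_h: float,
                                   elapsed_h: float) -> float:
    """Nominal chemostat generations g = D * t / ln 2 (config fallback when
    effluent volume was not recorded)."""
    return dilution_rate_per_h * elapsed_h / math.log(2)


def competition_coefficient(series: CompetitionSeries) -> FitnessEstimate:
    """OLS slope of ln(test/ref) on cumulative generations.

    Samples with a zero count on either side are dropped (logged upstream);
    at least 3 usable samples are required.
    """
    g, y = [], []
    for sample in series.samples:
        if sample.count_test == 0 or sample.count_ref == 0:
            continue
        g.append(generations(sample, series))
        y.append(math.log(sample.count_test / sample.count_ref))
    if len(g) < 3:
        raise EstimationError(
            f"{series.strain}/{series.environment}: only {len(g)} usable samples")
    fit = sps.linregress(g, y)
    return FitnessEstimate(s=float(fit.slope), se=float(fit.stderr),
                           r2=float(fit.rvalue) ** 2, n=len(g))


def normalize_to_ancestor(
    estimates: Mapping[str, Sequence[FitnessEstimate]],
    ancestor: str,
    atol: float = 1e-12,
) -> dict[str, float]:
    """Replicate-mean s per strain divided by the ancestor's replicate mean.

    The ancestor maps to exactly 1.  A near-zero ancestor mean is an error
    (reported, not silently propagated).
    """
    if ancestor not in estimates:
        raise EstimationError(f"ancestor {ancestor!r} missing from estimates")
    means = {strain: float(np.mean([e.s for e in reps]))
             for strain, reps in estimates.items()}
    if abs(means[ancestor]) <= atol:
        raise EstimationError("ancestor mean competition coefficient is zero")
    out = {strain: m / means[ancestor] for strain, m in means.items()}
    out[ancestor] = 1.0
    return out


def replicate_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-tailed Welch t-test p-value between replicate groups."""
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise EstimationError("need >= 2 replicates per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def max_growth_rate(time_h: Sequence[float], od: Sequence[float],
                    window: int = 5) -> float:
    """Maximum specific growth rate: the largest sliding-window OLS slope of
    ln(OD) versus time (h^-1).

    Non-positive OD points are dropped before windowing.
    """
    t = np.asarray(time_h, float)
    y = np.asarray(od, float)
    keep = y > 0
    t, y = t[keep], np.log(y[keep])
    if window < 2:
        raise ConfigError("window must be >= 2")
    if len(t) < window:
        raise EstimationError(f"need >= {window} positive-OD points, have {len(t)}")
    best = -math.inf
    for i in range(len(t) - window + 1):
        slope = sps.linregress(t[i : i + window], y[i : i + window]).slope
        best = max(best, float(slope))
    return best


def ddct_copy_number(sample: QpcrRecord | Iterable[QpcrRecord],
                     calibrator: QpcrRecord | Iterable[QpcrRecord]):
    """Relative copy number 2^(-ddCt) of a target locus.

    dCt = Ct(target) - Ct(control) per record; ddCt subtracts the
    calibrator's dCt.  With record lists, replicate dCt values are averaged
    first and the (mean, sd over sample replicates) pair is returned.
    """
    if isinstance(sample, QpcrRecord) and isinstance(calibrator, QpcrRecord):
        return 2.0 ** -(sample.delta_ct - calibrator.delta_ct)
    samples = [sample] if isinstance(sample, QpcrRecord) else list(sample)
    calibrators = ([calibrator] if isinstance(calibrator, QpcrRecord)
                   else list(calibrator))
    cal_dct = float(np.mean([r.delta_ct for r in calibrators]))
    values = [2.0 ** -(r.delta_ct - cal_dct) for r in samples]
    return float(np.mean(values)), float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
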