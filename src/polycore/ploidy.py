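"""Ploidy inference from the per-sample frequency of simplex/triplex calls.

A diploid genotyped on a tetraploid dosage scale can only produce balanced
calls {0, 2, 4}; dosage 1 and 3 calls (simplex/triplex) therefore occur at
near-zero frequency in diploids and at substantial frequency in tetraploids.
Classification thresholds default to: diploid if the frequency is <= 0.15,
tetraploid if > 0.20, unknown in the grey zone between.  Triploids cannot be
discriminated by this method and are never emitted as a class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .geno_io import MISSING, DosageMatrix, SampleMetadata, ValidationError

DIPLOID = "diploid"
TRIPLOID = "triploid"
TETRAPLOID = "tetraploid"
UNKNOWN = "unknown"

#: chromosome count -> reference ploidy class (Solanum base number 12)
_CHROM_TO_CLASS = {24: DIPLOID, 36: TRIPLOID, 48: TETRAPLOID}

DEFAULT_DIP_MAX = 0.15
DEFAULT_TET_MIN = 0.20


class ThresholdError(ValueError):
    """Invalid classification thresholds."""


@dataclass
class PloidyCall:
    sample_id: str
    st_freq: float
    call: str
    thresholds_used: tuple[float, float] = (DEFAULT_DIP_MAX, DEFAULT_TET_MIN)


@dataclass
class ClassStats:
    n_reference: int
    n_correct: int
    n_offtype: int
    accuracy_pct: Optional[float]  # None for unclassifiable classes
    mean_st_freq: float
    sd_st_freq: float


@dataclass
class ConcordanceReport:
    per_class: dict[str, ClassStats]
    anova_f: float
    anova_p: float

    @property
    def n_reference_total(self) -> int:
        return sum(c.n_reference for c in self.per_class.values())


@dataclass
class ReplicateConsistency:
    replicate_group: str
    calls: list[str]
    consistent: bool


@dataclass
class CalibrationResult:
    dip_max: float
    tet_min: float
    used_defaults: bool
    class_summary: dict[str, dict[str, float]] = field(default_factory=dict)


def simplex_triplex_frequency(sample_calls: np.ndarray) -> float:
    """Fraction of non-missing calls equal to 1 or 3."""
    calls = np.asarray(sample_calls)
    ok = calls != MISSING
    n = int(ok.sum())
    if n == 0:
        raise ValidationError("all calls missing; simplex/triplex frequency undefined")
    st = np.isin(calls[ok], (1, 3)).sum()
    return float(st) / n


def st_frequencies(matrix: DosageMatrix) -> np.ndarray:
    """Per-sample simplex+triplex frequencies for a whole matrix."""
    ok = ~matrix.missing_mask()
    n = ok.sum(axis=1)
    if (n == 0).any():
        bad = [s for s, k in zip(matrix.sample_ids, n) if k == 0]
        raise ValidationError(f"samples with all calls missing: {bad}")
    st = ((matrix.calls == 1) | (matrix.calls == 3)).sum(axis=1)
    return st / n


def classify_ploidy(
    st_freq: float,
    dip_max: float = DEFAULT_DIP_MAX,
    tet_min: float = DEFAULT_TET_MIN,
) -> str:
    """Classify one simplex/triplex frequency.

    Boundary convention: ``st_freq == dip_max`` is diploid; ``st_freq ==
    tet_min`` is unknown (closed lower class, open upper class).
    """
    if dip_max >= tet_min:
        raise ThresholdError(f"dip_max ({dip_max}) must be < tet_min ({tet_min})")
    if not 0.0 <= st_freq <= 1.0:
        raise ValueError(f"st_freq {st_freq} outside [0, 1]")
    if st_freq <= dip_max:
        return DIPLOID
    if st_freq > tet_min:
        return TETRAPLOID
    return UNKNOWN


def call_ploidy(
    matrix: DosageMatrix,
    dip_max: float = DEFAULT_DIP_MAX,
    tet_min: float = DEFAULT_TET_MIN,
) -> list[PloidyCall]:
    freqs = st_frequencies(matrix)
    return [
        PloidyCall(sid, float(f), classify_ploidy(float(f), dip_max, tet_min), (dip_max, tet_min))
        for sid, f in zip(matrix.sample_ids, freqs)
    ]


def reference_class(meta: SampleMetadata) -> Optional[str]:
    """Reference ploidy class from a chromosome count, if interpretable."""
    if meta.chromosome_count is None:
        return None
    return _CHROM_TO_CLASS.get(meta.chromosome_count)


def concordance(
    ploidy_calls: Sequence[PloidyCall],
    reference_metadata: Sequence[SampleMetadata],
) -> ConcordanceReport:
    """Compare frequency-based calls against chromosome-count reference ploidy.

    Accuracy is reported per class at one-decimal rounding.  Triploids are
    unclassifiable by this method: they are counted and summarized but get no
    accuracy figure, and do not enter other classes' denominators.
    """
    by_id = {c.sample_id: c for c in ploidy_calls}
    ref = [
        (m.sample_id, reference_class(m))
        for m in reference_metadata
        if reference_class(m) is not None and m.sample_id in by_id
    ]
    if not ref:
        raise ValidationError("empty reference panel")

    per_class: dict[str, ClassStats] = {}
    groups: dict[str, list[float]] = {}
    for cls in (DIPLOID, TRIPLOID, TETRAPLOID):
        members = [by_id[sid] for sid, c in ref if c == cls]
        if not members:
            continue
        freqs = [m.st_freq for m in members]
        groups[cls] = freqs
        if cls == TRIPLOID:
            acc, n_correct = None, 0
            n_off = len(members)
        else:
            n_correct = sum(1 for m in members if m.call == cls)
            n_off = len(members) - n_correct
            acc = round(100.0 * n_correct / len(members), 1)
        per_class[cls] = ClassStats(
            n_reference=len(members),
            n_correct=n_correct,
            n_offtype=n_off,
            accuracy_pct=acc,
            mean_st_freq=float(np.mean(freqs)),
            sd_st_freq=float(np.std(freqs, ddof=1)) if len(freqs) > 1 else 0.0,
        )

    usable = [g for g in groups.values() if len(g) >= 2]
    if len(usable) >= 2:
        f_stat, p = anova_oneway(usable)
    else:
        f_stat, p = math.nan, math.nan
    return ConcordanceReport(per_class=per_class, anova_f=f_stat, anova_p=p)


def calibrate_thresholds(
    reference_st_freqs: Sequence[float],
    reference_classes: Sequence[str],
    trim: float = 0.05,
) -> CalibrationResult:
    """Propose (dip_max, tet_min) from a reference panel.

    Rule: trim the top ``trim`` fraction of diploid frequencies as off-types
    and take their max as dip_max; trim the bottom ``trim`` fraction of
    tetraploid frequencies and take their min as tet_min.  If the trimmed
    ranges overlap, warn and fall back to the defaults (0.15, 0.20).
    Class-conditional summaries are always returned so a curator can
    override.
    """
    freqs = np.asarray(reference_st_freqs, dtype=float)
    classes = np.asarray(reference_classes)
    summary: dict[str, dict[str, float]] = {}
    for cls in sorted(set(classes)):
        vals = freqs[classes == cls]
        summary[cls] = {
            "n": int(vals.size),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        }
    dip = np.sort(freqs[classes == DIPLOID])
    tet = np.sort(freqs[classes == TETRAPLOID])
    if dip.size < 2 or tet.size < 2:
        raise ValidationError(
            "calibration needs >=2 reference samples in each of the diploid "
            "and tetraploid classes"
        )
    n_trim_d = int(math.floor(trim * dip.size))
    n_trim_t = int(math.floor(trim * tet.size))
    dip_max = float(dip[: dip.size - n_trim_d][-1])
    tet_min = float(tet[n_trim_t:][0])
    if dip_max >= tet_min:
        warnings.warn(
            "diploid and tetraploid frequency ranges overlap after trimming; "
            "falling back to default thresholds"
        )
        return CalibrationResult(
            DEFAULT_DIP_MAX, DEFAULT_TET_MIN, used_defaults=True, class_summary=summary
        )
    return CalibrationResult(dip_max, tet_min, used_defaults=False, class_summary=summary)


def anova_oneway(groups: Iterable[Sequence[float]]) -> tuple[float, float]:
    """Classic one-way ANOVA (F statistic, p-value).

    All-constant groups with zero within-group variance but distinct means
    give infinite F, reported with p = 0.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrs):
        raise ValidationError("every ANOVA group needs n >= 2")
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrs)
    grand = np.concatenate(arrs).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    df_b = len(arrs) - 1
    df_w = sum(a.size for a in arrs) - len(arrs)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def replicate_consistency(
    ploidy_calls: Sequence[PloidyCall],
    metadata: Sequence[SampleMetadata],
) -> list[ReplicateConsistency]:
    """Check that biological replicates received the same ploidy call.

    A group is consistent when all its non-unknown calls agree; unknown
    calls are ignored.
    """
    by_id = {c.sample_id: c for c in ploidy_calls}
    groups: dict[str, list[str]] = {}
    for m in metadata:
        if m.replicate_group is not None and m.sample_id in by_id:
            groups.setdefault(m.replicate_group, []).append(by_id[m.sample_id].call)
    out = []
    for name in sorted(groups):
        calls = groups[name]
        if len(calls) < 2:
            continue
        definite = {c for c in calls if c != UNKNOWN}
        out.append(
            ReplicateConsistency(
                replicate_group=name, calls=calls, consistent=len(definite) <= 1
            )
        )
    return out
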