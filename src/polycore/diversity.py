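"""Dosage-based diversity statistics: Ho, Modified Rogers distance, FST, AMOVA."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geno_io import MISSING, DosageMatrix, ValidationError


@dataclass
class HoResult:
    """Per-sample observed heterozygosity with optional per-group summaries."""

    sample_ids: list[str]
    ho: np.ndarray
    group_means: dict[str, tuple[float, float]] = field(default_factory=dict)

    def mean(self) -> float:
        return float(np.mean(self.ho))

    def sd(self) -> float:
        return float(np.std(self.ho, ddof=1)) if len(self.ho) > 1 else 0.0


@dataclass
class DistanceMatrix:
    """Symmetric accession x accession distance matrix."""

    ids: list[str]
    values: np.ndarray
    metric_name: str = "MRD"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValidationError("distance matrix diagonal not zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, item: str) -> int:
        return self.ids.index(item)

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in keep]
        return DistanceMatrix(list(keep), self.values[np.ix_(idx, idx)], self.metric_name)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, metric_name: str = "MRD") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), metric_name)


@dataclass
class AmovaResult:
    phi: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    p_value: float
    n_permutations: int
    negative_component_truncated: bool = False


@dataclass
class FstResult:
    """Pairwise group FST with permutation p-values, keyed by (group_a, group_b)."""

    fst: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    n_permutations: int

    def get(self, a: str, b: str) -> float:
        key = (a, b) if (a, b) in self.fst else (b, a)
        return self.fst[key]


def observed_heterozygosity(
    matrix: DosageMatrix,
    group_labels: Optional[Sequence[str]] = None,
) -> HoResult:
    """Fraction of non-missing calls per sample that are heterozygous (1, 2, 3)."""
    ok = ~matrix.missing_mask()
    n = ok.sum(axis=1)
    if (n == 0).any():
        bad = [s for s, k in zip(matrix.sample_ids, n) if k == 0]
        raise ValidationError(f"samples with all calls missing: {bad}")
    het = np.isin(matrix.calls, (1, 2, 3)) & ok
    ho = het.sum(axis=1) / n
    result = HoResult(list(matrix.sample_ids), ho)
    if group_labels is not None:
        labels = np.asarray(group_labels)
        for g in sorted(set(labels)):
            vals = ho[labels == g]
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            result.group_means[str(g)] = (float(np.mean(vals)), sd)
    return result


def mrd_matrix(matrix: DosageMatrix) -> DistanceMatrix:
    """Modified Rogers distance on within-individual allele frequencies.

    With p = dosage/4, d(i,j) = sqrt( sum_l (p_il - p_jl)^2 / L_ij ) over the
    L_ij markers non-missing in both samples.  For biallelic loci this equals
    the classical (1/sqrt(2L)) * sqrt(sum over loci and alleles of the
    squared frequency differences), and is bounded in [0, 1].
    """
    if matrix.n_samples < 2:
        raise ValidationError("need at least two samples for a distance matrix")
    p = matrix.calls.astype(float) / 4.0
    p[matrix.missing_mask()] = np.nan
    n = matrix.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        diff = p[i] - p[i:]
        shared = ~np.isnan(diff)
        l_ij = shared.sum(axis=1)
        if (l_ij == 0).any():
            j = i + int(np.argmax(l_ij == 0))
            raise ValidationError(
                f"samples {matrix.sample_ids[i]!r} and {matrix.sample_ids[j]!r} "
                "share no non-missing marker"
            )
        ss = np.nansum(diff**2, axis=1)
        d[i, i:] = np.sqrt(ss / l_ij)
    d = d + d.T
    return DistanceMatrix(list(matrix.sample_ids), d, "MRD")


def _group_allele_freqs(calls: np.ndarray) -> np.ndarray:
    """Per-marker ALT frequency for one group's calls (NaN if all missing)."""
    c = calls.astype(float)
    c[calls == MISSING] = np.nan
    n_ok = np.sum(~np.isnan(c), axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(c, axis=0) / (4.0 * n_ok)
    p[n_ok == 0] = np.nan
    return p


def fst_from_freqs(p_groups: np.ndarray) -> float:
    """Nei-style FST from a groups x markers allele-frequency array.

    Per locus, H_S = mean over groups of 2pq and H_T = 2 p_bar q_bar; FST is
    the mean over loci with H_T > 0 of (H_T - H_S) / H_T.
    """
    p = np.asarray(p_groups, dtype=float)
    h_s = np.nanmean(2.0 * p * (1.0 - p), axis=0)
    p_bar = np.nanmean(p, axis=0)
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    ok = np.isfinite(h_t) & (h_t > 0)
    if not ok.any():
        raise ValidationError("all loci monomorphic: FST undefined")
    return float(np.mean((h_t[ok] - h_s[ok]) / h_t[ok]))


def nei_fst(
    matrix: DosageMatrix,
    group_labels: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> FstResult:
    """Pairwise Nei-style FST between groups, with label-permutation p-values."""
    labels = np.asarray([str(g) for g in group_labels])
    if labels.size != matrix.n_samples:
        raise ValidationError("group label length mismatch")
    names = sorted(set(labels))
    if len(names) < 2:
        raise ValidationError("need at least two groups")
    for g in names:
        if (labels == g).sum() < 2:
            raise ValidationError(f"group {g!r} has fewer than two samples")

    rng = np.random.default_rng(seed)
    fst: dict[tuple[str, str], float] = {}
    pvals: dict[tuple[str, str], float] = {}
    for ai in range(len(names)):
        for bi in range(ai + 1, len(names)):
            a, b = names[ai], names[bi]
            sel = (labels == a) | (labels == b)
            sub = matrix.calls[sel]
            sub_labels = labels[sel]
            is_a = sub_labels == a
            p_a = _group_allele_freqs(sub[is_a])
            p_b = _group_allele_freqs(sub[~is_a])
            obs = fst_from_freqs(np.vstack([p_a, p_b]))
            n_ge = 0
            perm_mask = is_a.copy()
            for _ in range(n_perm):
                rng.shuffle(perm_mask)
                f = fst_from_freqs(
                    np.vstack(
                        [
                            _group_allele_freqs(sub[perm_mask]),
                            _group_allele_freqs(sub[~perm_mask]),
                        ]
                    )
                )
                if f >= obs:
                    n_ge += 1
            fst[(a, b)] = obs
            pvals[(a, b)] = (n_ge + 1) / (n_perm + 1)
    return FstResult(fst=fst, p_values=pvals, n_permutations=n_perm)


def _amova_ss(d2: np.ndarray, labels: np.ndarray, names: list[str]) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in names:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def amova(
    dist: DistanceMatrix,
    group_labels: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """One-level distance-based AMOVA with a permutation test on Phi.

    Sums of squares come from squared distances (total SS = sum_{i<j} d^2 / N,
    within SS summed per group); variance components use the standard
    coefficient n0 = (N - sum n_g^2 / N) / (g - 1).  A negative among-group
    component is truncated at zero and flagged.  The p-value is the fraction
    of label permutations with Phi >= the observed value, with the +1
    correction, so its floor is 1/(n_perm+1).
    """
    labels = np.asarray([str(g) for g in group_labels])
    if labels.size != dist.n:
        raise ValidationError("group label length mismatch")
    names = sorted(set(labels))
    if len(names) < 2:
        raise ValidationError("need at least two groups")
    sizes = {g: int((labels == g).sum()) for g in names}
    for g, k in sizes.items():
        if k < 2:
            raise ValidationError(f"group {g!r} has fewer than two samples")

    d2 = dist.values**2
    n = dist.n
    g = len(names)
    df_among = g - 1
    df_within = n - g
    n0 = (n - sum(k**2 for k in sizes.values()) / n) / df_among

    def phi_of(lab: np.ndarray) -> tuple[float, float, float, bool]:
        ss_total, ss_within = _amova_ss(d2, lab, names)
        ss_among = ss_total - ss_within
        ms_among = ss_among / df_among
        ms_within = ss_within / df_within
        s2_within = ms_within
        s2_among = (ms_among - ms_within) / n0
        truncated = s2_among < 0
        if truncated:
            s2_among = 0.0
        tot = s2_among + s2_within
        phi = s2_among / tot if tot > 0 else 0.0
        return phi, s2_among, s2_within, truncated

    phi_obs, s2_a, s2_w, truncated = phi_of(labels)
    rng = np.random.default_rng(seed)
    n_ge = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if phi_of(perm)[0] >= phi_obs:
            n_ge += 1
    p = (n_ge + 1) / (n_perm + 1)
    tot = s2_a + s2_w
    pct_among = 100.0 * s2_a / tot if tot > 0 else 0.0
    return AmovaResult(
        phi=phi_obs,
        sigma2_among=s2_a,
        sigma2_within=s2_w,
        pct_among=pct_among,
        pct_within=100.0 - pct_among,
        p_value=p,
        n_permutations=n_perm,
        negative_component_truncated=truncated,
    )
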