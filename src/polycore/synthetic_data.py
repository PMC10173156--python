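"""Seeded simulation of mixed-ploidy dosage panels with known ground truth.

The generative model: per marker an ancestral frequency is drawn from
Uniform(low, high); each group's frequency diverges under the
Balding-Nichols Beta model with its own F; dosage calls are binomial in the
sample's true ploidy, re-expressed on the 0..4 tetraploid scale (diploids
emit {0,2,4}; triploids round(4g/3) -> {0,1,3,4}).  Genotyping error shifts
a call by +/-1 (clamped) with probability e; missing calls and biological
replicate pairs are then layered on.  Everything is driven by one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geno_io import (
    MISSING,
    DosageMatrix,
    PhenotypeTable,
    SampleMetadata,
    ValidationError,
)


@dataclass
class SyntheticPanelConfig:
    group_sizes: tuple[int, ...] = (60, 120)
    group_ploidy: tuple[int, ...] = (2, 4)
    n_markers: int = 1000
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    divergence: tuple[float, ...] | float = 0.25  # Balding-Nichols F per group
    miscall_rate: float = 0.0
    missing_rate: float = 0.0
    n_replicate_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(self.group_ploidy):
            raise ValidationError("group_sizes and group_ploidy length mismatch")
        if any(s < 1 for s in self.group_sizes):
            raise ValidationError("group sizes must be >= 1")
        if any(p not in (2, 3, 4) for p in self.group_ploidy):
            raise ValidationError("ploidies must be in {2, 3, 4}")
        if self.n_markers < 1:
            raise ValidationError("need at least one marker")
        if isinstance(self.divergence, (int, float)):
            self.divergence = tuple([float(self.divergence)] * len(self.group_sizes))
        if len(self.divergence) != len(self.group_sizes):
            raise ValidationError("divergence length mismatch")
        for r in (self.miscall_rate, self.missing_rate, *self.divergence):
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"rate {r} outside [0, 1]")

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)


@dataclass
class GroundTruth:
    sample_ids: list[str]
    labels: list[int]  # group index per sample (replicates share their source's)
    ploidies: list[int]
    group_freqs: np.ndarray  # groups x markers
    config: SyntheticPanelConfig
    phenotype_params: dict = field(default_factory=dict)


def _dosage_for_ploidy(rng: np.random.Generator, ploidy: int, p: np.ndarray) -> np.ndarray:
    g = rng.binomial(ploidy, p)
    if ploidy == 4:
        return g.astype(np.int8)
    if ploidy == 2:
        return (2 * g).astype(np.int8)
    # triploid: rescale 0..3 onto the tetraploid axis -> {0, 1, 3, 4}
    return np.rint(4.0 * g / 3.0).astype(np.int8)


def simulate_panel(
    config: SyntheticPanelConfig,
) -> tuple[DosageMatrix, list[SampleMetadata], GroundTruth]:
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, config.n_markers)

    group_freqs = np.empty((config.n_groups, config.n_markers))
    for k, f in enumerate(config.divergence):
        if f == 0.0:
            group_freqs[k] = p_anc
        else:
            a = p_anc * (1.0 - f) / f
            b = (1.0 - p_anc) * (1.0 - f) / f
            group_freqs[k] = rng.beta(a, b)

    sample_ids: list[str] = []
    labels: list[int] = []
    ploidies: list[int] = []
    true_calls: list[np.ndarray] = []
    i = 0
    for k, (size, ploidy) in enumerate(zip(config.group_sizes, config.group_ploidy)):
        for _ in range(size):
            i += 1
            sample_ids.append(f"S{i:04d}")
            labels.append(k)
            ploidies.append(ploidy)
            true_calls.append(_dosage_for_ploidy(rng, ploidy, group_freqs[k]))

    replicate_group: dict[str, str] = {}
    n_rep = min(config.n_replicate_pairs, len(sample_ids))
    if n_rep:
        chosen = rng.choice(len(sample_ids), size=n_rep, replace=False)
        for j in sorted(int(c) for c in chosen):
            src = sample_ids[j]
            rep_id = f"{src}r"
            sample_ids.append(rep_id)
            labels.append(labels[j])
            ploidies.append(ploidies[j])
            true_calls.append(true_calls[j].copy())
            replicate_group[src] = src
            replicate_group[rep_id] = src

    calls = np.vstack(true_calls)
    if config.miscall_rate > 0:
        hit = rng.random(calls.shape) < config.miscall_rate
        shift = rng.choice((-1, 1), size=calls.shape)
        calls = np.where(hit, np.clip(calls + shift, 0, 4), calls).astype(np.int8)
    if config.missing_rate > 0:
        calls = np.where(
            rng.random(calls.shape) < config.missing_rate, MISSING, calls
        ).astype(np.int8)

    matrix = DosageMatrix(sample_ids, [f"M{j:05d}" for j in range(1, config.n_markers + 1)], calls)
    meta = [
        SampleMetadata(
            sample_id=sid,
            taxon_label=f"group{labels[j] + 1}",
            origin="simulated",
            replicate_group=replicate_group.get(sid),
        )
        for j, sid in enumerate(sample_ids)
    ]
    truth = GroundTruth(
        sample_ids=list(sample_ids),
        labels=labels,
        ploidies=ploidies,
        group_freqs=group_freqs,
        config=config,
    )
    return matrix, meta, truth


#: generative defaults for reference chloroplast counts (mean, sd) per ploidy
CHLOROPLAST_PARAMS = {2: (7.6, 0.83), 3: (10.0, 1.0), 4: (13.2, 1.06)}


def simulate_reference_panel(
    metadata: Sequence[SampleMetadata],
    truth: GroundTruth,
    seed: Optional[int] = None,
) -> list[SampleMetadata]:
    """Attach reference chromosome and chloroplast counts to panel metadata.

    chromosome_count = 12 x ploidy exactly; chloroplast_count is normal with
    ploidy-specific means/sds (triploid parameters are a midpoint stand-in).
    """
    rng = np.random.default_rng(truth.config.seed + 1 if seed is None else seed)
    out = []
    for m, ploidy in zip(metadata, truth.ploidies):
        mean, sd = CHLOROPLAST_PARAMS[ploidy]
        chloro = max(0.5, float(rng.normal(mean, sd)))
        out.append(
            SampleMetadata(
                sample_id=m.sample_id,
                taxon_label=m.taxon_label,
                origin=m.origin,
                replicate_group=m.replicate_group,
                chromosome_count=12 * ploidy,
                chloroplast_count=chloro,
            )
        )
    return out


DEFAULT_TRAIT_BASES = {"ATW": 20.0, "NTP": 12.0, "TTY": 0.8}


def simulate_phenotypes(
    truth: GroundTruth,
    seed: Optional[int] = None,
    trait_bases: Optional[dict[str, float]] = None,
    group_spread: float = 1.0,
    noise_cv: float = 0.25,
    missing_rate: float = 0.0,
) -> PhenotypeTable:
    """Group-structured trait values: group mean + normal noise, clamped at 0.

    Group means for each trait are spread multiplicatively around the trait
    base; with ``group_spread = 1`` the between-group variance is comparable
    to the within-group variance, so a one-way ANOVA on groups rejects easily
    at default panel sizes.
    """
    bases = dict(DEFAULT_TRAIT_BASES if trait_bases is None else trait_bases)
    rng = np.random.default_rng(truth.config.seed + 2 if seed is None else seed)
    n = len(truth.labels)
    labels = np.asarray(truth.labels)
    k = truth.config.n_groups
    traits = list(bases)
    values = np.empty((n, len(traits)))
    params: dict[str, list[float]] = {}
    for t_i, trait in enumerate(traits):
        base = bases[trait]
        offsets = np.linspace(-0.5, 0.5, k) * group_spread if k > 1 else np.zeros(1)
        group_means = base * (1.0 + offsets)
        params[trait] = group_means.tolist()
        noise = rng.normal(0.0, base * noise_cv, n)
        values[:, t_i] = np.clip(group_means[labels] + noise, 0.0, None)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        # keep the at-least-one-trait invariant per row
        all_gone = mask.all(axis=1)
        mask[all_gone, 0] = False
        values[mask] = np.nan
    truth.phenotype_params = {"group_means": params, "noise_cv": noise_cv}
    return PhenotypeTable(
        accession_ids=list(truth.sample_ids), traits=traits, values=values
    )
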