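"""Phenotypic validation of core selections: Gower distances and summaries."""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_select import CoreSelection, ane_objective, ee_objective, ene_objective
from .diversity import DistanceMatrix
from .geno_io import PhenotypeTable, ValidationError


def gower_distance(pheno: PhenotypeTable) -> DistanceMatrix:
    """Gower distance on numeric traits: range-normalized mean absolute difference.

    Trait ranges are taken over the whole table (not per subset), so subset
    and whole-collection distances are comparable.  Traits with zero range
    are dropped with a warning; a pair sharing no non-missing trait is an
    error.
    """
    if len(pheno.accession_ids) < 2:
        raise ValidationError("need at least two accessions")
    x = pheno.values.astype(float)
    rng = np.nanmax(x, axis=0) - np.nanmin(x, axis=0)
    keep = rng > 0
    if not keep.all():
        dropped = [t for t, k in zip(pheno.traits, keep) if not k]
        warnings.warn(f"dropping zero-range trait(s): {dropped}")
    if not keep.any():
        raise ValidationError("no trait with nonzero range")
    x = x[:, keep]
    rng = rng[keep]

    n = x.shape[0]
    d = np.zeros((n, n))
    scaled = x / rng
    for i in range(n):
        diff = np.abs(scaled[i] - scaled[i:])
        shared = ~np.isnan(diff)
        n_shared = shared.sum(axis=1)
        if (n_shared == 0).any():
            j = i + int(np.argmax(n_shared == 0))
            raise ValidationError(
                f"accessions {pheno.accession_ids[i]!r} and "
                f"{pheno.accession_ids[j]!r} share no non-missing trait"
            )
        d[i, i:] = np.nansum(diff, axis=1) / n_shared
    d = d + d.T
    return DistanceMatrix(list(pheno.accession_ids), d, "Gower")


def summary_stats(
    pheno: PhenotypeTable,
    collections: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per collection x trait: n, mean, median, sd, CV (%), min, max.

    Entry sets are intersected with the phenotyped accessions; the sample
    (n-1) standard deviation is used and CV = 100*sd/mean when mean != 0.
    """
    df = pheno.to_frame()
    rows = []
    for name, entries in collections.items():
        present = [e for e in entries if e in df.index]
        if not present:
            raise ValidationError(f"collection {name!r} has no phenotyped accession")
        sub = df.loc[present]
        for trait in pheno.traits:
            vals = sub[trait].dropna().to_numpy()
            if vals.size == 0:
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            rows.append(
                {
                    "collection": name,
                    "trait": trait,
                    "n": int(vals.size),
                    "mean": mean,
                    "median": float(np.median(vals)),
                    "sd": sd,
                    "cv_pct": 100.0 * sd / mean if mean != 0 else np.nan,
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                }
            )
    return pd.DataFrame(rows)


def evaluate_cores_pheno(
    gower_dist: DistanceMatrix,
    selections: Mapping[float, Sequence[str] | CoreSelection],
) -> pd.DataFrame:
    """A-NE/E-NE/E-E of genotype-selected entries on the phenotype distances.

    Each selection is intersected with the phenotyped accessions; selections
    left with fewer than two phenotyped entries are skipped with a warning.
    """
    rows = []
    known = set(gower_dist.ids)
    for fraction in sorted(selections):
        sel = selections[fraction]
        entries = sel.entry_ids if isinstance(sel, CoreSelection) else list(sel)
        present = [e for e in entries if e in known]
        if len(present) < 2:
            warnings.warn(
                f"selection at fraction {fraction} has <2 phenotyped entries; skipped"
            )
            continue
        rows.append(
            {
                "fraction": fraction,
                "n_entries": len(present),
                "A_NE": ane_objective(gower_dist, present),
                "E_NE": ene_objective(gower_dist, present),
                "E_E": ee_objective(gower_dist, present),
            }
        )
    return pd.DataFrame(rows)
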