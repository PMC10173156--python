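"""Core-collection selection by accession-to-nearest-entry minimization.

The optimizer is a seeded multi-start swap local search: from a greedy
(medoid-style) initialization plus random restarts, it repeatedly applies
the single entry/non-entry swap that most lowers the A-NE objective until no
improving swap exists.  Scan order and tie-breaking follow ascending
accession index, so runs are reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix
from .geno_io import ValidationError


@dataclass
class CoreSelection:
    entry_ids: list[str]
    fraction: float
    objective_values: dict[str, float] = field(default_factory=dict)
    optimizer_trace: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.entry_ids)) != len(self.entry_ids):
            raise ValidationError("duplicate entries in core selection")


def core_size(n: int, fraction: float) -> int:
    """Number of entries for a size fraction: nearest integer, half rounds up."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction {fraction} outside (0, 1]")
    k = int(np.floor(fraction * n + 0.5))
    return max(1, min(k, n))


def _entry_indices(dist: DistanceMatrix, entries: Sequence[str]) -> np.ndarray:
    try:
        return np.array([dist.ids.index(e) for e in entries], dtype=int)
    except ValueError as exc:
        raise ValidationError(f"unknown entry id: {exc}") from None


def ane_objective(dist: DistanceMatrix, entries: Sequence[str]) -> float:
    """Mean over all accessions of the distance to the nearest entry."""
    if len(entries) == 0:
        raise ValidationError("entry set is empty")
    idx = _entry_indices(dist, entries)
    return float(dist.values[:, idx].min(axis=1).mean())


def ene_objective(dist: DistanceMatrix, entries: Sequence[str]) -> float:
    """Mean over entries of the distance to the nearest *other* entry."""
    if len(entries) < 2:
        raise ValidationError("E-NE needs at least two entries")
    idx = _entry_indices(dist, entries)
    sub = dist.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def ee_objective(dist: DistanceMatrix, entries: Sequence[str]) -> float:
    """Mean distance over unordered pairs of entries."""
    if len(entries) < 2:
        raise ValidationError("E-E needs at least two entries")
    idx = _entry_indices(dist, entries)
    sub = dist.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def _ane(d: np.ndarray, entry_idx: np.ndarray) -> float:
    return float(d[:, entry_idx].min(axis=1).mean())


def _greedy_init(d: np.ndarray, k: int) -> np.ndarray:
    """Medoid first, then repeatedly add the accession that most lowers A-NE."""
    n = d.shape[0]
    entries = [int(np.argmin(d.mean(axis=1)))]
    dmin = d[:, entries[0]].copy()
    while len(entries) < k:
        cand = np.setdiff1d(np.arange(n), entries, assume_unique=False)
        # objective after adding each candidate, vectorized over candidates
        new_obj = np.minimum(d[:, cand], dmin[:, None]).mean(axis=0)
        best = cand[int(np.argmin(new_obj))]
        entries.append(int(best))
        dmin = np.minimum(dmin, d[:, best])
    return np.array(sorted(entries), dtype=int)


def _local_search(
    d: np.ndarray, entry_idx: np.ndarray, max_moves: int
) -> tuple[np.ndarray, float, int]:
    """Steepest-improvement swap search to a local A-NE optimum."""
    n = d.shape[0]
    entries = np.array(sorted(entry_idx), dtype=int)
    moves = 0
    obj = _ane(d, entries)
    while moves < max_moves:
        sub = d[:, entries]  # n x k
        order = np.argsort(sub, axis=1)
        d1 = sub[np.arange(n), order[:, 0]]
        nearest = entries[order[:, 0]]
        if len(entries) > 1:
            d2 = sub[np.arange(n), order[:, 1]]
        else:
            d2 = np.full(n, np.inf)
        cand = np.setdiff1d(np.arange(n), entries, assume_unique=False)
        if cand.size == 0:
            break
        best_obj = obj
        best_swap = None
        for e in entries:
            base = np.where(nearest == e, d2, d1)
            new_obj = np.minimum(d[:, cand], base[:, None]).mean(axis=0)
            j = int(np.argmin(new_obj))
            if new_obj[j] < best_obj - 1e-12:
                best_obj = float(new_obj[j])
                best_swap = (int(e), int(cand[j]))
        if best_swap is None:
            break
        e_out, c_in = best_swap
        entries = np.array(sorted(set(entries.tolist()) - {e_out} | {c_in}), dtype=int)
        obj = best_obj
        moves += 1
    return entries, obj, moves


def select_core(
    dist: DistanceMatrix,
    k: int,
    seed: int = 0,
    n_restarts: int = 20,
    max_no_improve: int = 1000,
) -> CoreSelection:
    """Select ``k`` entries minimizing A-NE by multi-start swap local search.

    Restart 0 starts from the greedy medoid-style initialization; the
    remaining restarts start from seeded random subsets.  The best local
    optimum across restarts is returned.  The returned objective never
    exceeds that of any initialization (the search only ever improves).
    """
    n = dist.n
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} outside 1..{n}")
    d = dist.values
    rng = np.random.default_rng(seed)

    best_entries: np.ndarray | None = None
    best_obj = np.inf
    trace = {"seed": seed, "restarts": n_restarts, "moves": [], "init_objectives": []}
    for r in range(max(1, n_restarts)):
        init = _greedy_init(d, k) if r == 0 else np.sort(rng.choice(n, size=k, replace=False))
        trace["init_objectives"].append(_ane(d, init))
        entries, obj, moves = _local_search(d, init, max_no_improve)
        trace["moves"].append(moves)
        if obj < best_obj - 1e-15:
            best_obj = obj
            best_entries = entries
    assert best_entries is not None
    entry_ids = [dist.ids[i] for i in best_entries]
    objectives = {"A_NE": best_obj}
    if k >= 2:
        objectives["E_NE"] = ene_objective(dist, entry_ids)
        objectives["E_E"] = ee_objective(dist, entry_ids)
    return CoreSelection(
        entry_ids=entry_ids,
        fraction=k / n,
        objective_values=objectives,
        optimizer_trace=trace,
    )


def nest_minicore(
    mini_entries: Sequence[str],
    core_entries: Sequence[str],
    dist: DistanceMatrix,
) -> list[str]:
    """Replace mini-core entries so the mini-core nests inside the core.

    Mini entries already in the core are kept.  Each remaining mini entry is
    replaced by its nearest not-yet-used core entry; pending replacements are
    processed in ascending order of that replacement distance (ties by
    ascending id), so when two mini entries share a nearest core entry the
    nearer one claims it.
    """
    if len(mini_entries) > len(core_entries):
        raise ValidationError("mini-core larger than core")
    core_set = list(dict.fromkeys(core_entries))
    kept = [m for m in mini_entries if m in core_set]
    used = set(kept)
    pending = [m for m in mini_entries if m not in core_set]
    result = list(kept)
    while pending:
        candidates = []
        for m in pending:
            free = [c for c in core_set if c not in used]
            dists = [(dist.values[dist.index(m), dist.index(c)], c) for c in free]
            d_best, c_best = min(dists, key=lambda t: (t[0], t[1]))
            candidates.append((d_best, m, c_best))
        _, m_sel, c_sel = min(candidates, key=lambda t: (t[0], t[1]))
        result.append(c_sel)
        used.add(c_sel)
        pending.remove(m_sel)
    return result


def evaluate_cores(
    dist: DistanceMatrix,
    selections: Mapping[float, Sequence[str] | CoreSelection],
) -> pd.DataFrame:
    """A-NE / E-NE / E-E per size fraction, as a tidy table."""
    rows = []
    for fraction in sorted(selections):
        sel = selections[fraction]
        entries = sel.entry_ids if isinstance(sel, CoreSelection) else list(sel)
        row = {
            "fraction": fraction,
            "n_entries": len(entries),
            "A_NE": ane_objective(dist, entries),
        }
        if len(entries) >= 2:
            row["E_NE"] = ene_objective(dist, entries)
            row["E_E"] = ee_objective(dist, entries)
        else:
            row["E_NE"] = np.nan
            row["E_E"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
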