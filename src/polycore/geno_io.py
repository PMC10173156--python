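"""Reading, validation, filtering and writing of allele-dosage genotype matrices.

Genotypes are tetraploid-scale dosage calls: the count 0..4 of the alternate
(B) allele at a biallelic marker.  The matrix is oriented samples x markers
throughout the package.  Missing calls are stored as :data:`MISSING` (-1) in
an integer array; the TSV representation uses the token ``NA`` and VCF uses
``.`` alleles.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing dosage call inside ``DosageMatrix.calls``.
MISSING: int = -1

_MISSING_TOKEN = "NA"


class GenotypeParseError(ValueError):
    """A cell or record could not be interpreted as a dosage call."""


class ValidationError(ValueError):
    """A structural invariant of a domain object is violated."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class DosageMatrix:
    """Samples x markers matrix of integer dosage calls in 0..4.

    Parameters
    ----------
    sample_ids, marker_ids
        Ordered, unique identifiers for rows and columns.
    calls
        Integer array of shape ``(n_samples, n_markers)``; entries are in
        ``{0,1,2,3,4}`` or :data:`MISSING`.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValidationError("calls must be a 2-D array")
        if self.calls.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.marker_ids, "marker")
        bad = (self.calls != MISSING) & ((self.calls < 0) | (self.calls > 4))
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"dosage out of range at sample {self.sample_ids[r]!r}, "
                f"marker {self.marker_ids[c]!r}: {int(self.calls[r, c])}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def subset_samples(self, keep: Sequence[str]) -> "DosageMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return DosageMatrix(list(keep), list(self.marker_ids), self.calls[idx, :])

    def subset_markers(self, keep: Sequence[str]) -> "DosageMatrix":
        idx = [self.marker_ids.index(m) for m in keep]
        return DosageMatrix(list(self.sample_ids), list(keep), self.calls[:, idx])


@dataclass
class SampleMetadata:
    """Per-sample passport and reference-ploidy information."""

    sample_id: str
    taxon_label: str = "unknown"
    origin: str = "unknown"
    replicate_group: Optional[str] = None
    chromosome_count: Optional[int] = None
    chloroplast_count: Optional[float] = None

    def __post_init__(self) -> None:
        if self.chromosome_count is not None and self.chromosome_count <= 0:
            raise ValidationError(
                f"chromosome_count must be positive for {self.sample_id!r}"
            )
        if self.chloroplast_count is not None and self.chloroplast_count <= 0:
            raise ValidationError(
                f"chloroplast_count must be positive for {self.sample_id!r}"
            )


@dataclass
class PhenotypeTable:
    """Per-accession trait values (grams, count, kg/plant); NaN = missing."""

    accession_ids: list[str]
    traits: list[str]
    values: np.ndarray  # float, NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.accession_ids), len(self.traits)):
            raise ValidationError("phenotype values shape mismatch")
        _check_unique(self.accession_ids, "accession")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values, initial=0.0) < 0:
                raise ValidationError("negative trait value")
        all_missing = np.isnan(self.values).all(axis=1)
        if all_missing.any():
            bad = [a for a, m in zip(self.accession_ids, all_missing) if m]
            raise ValidationError(f"rows with no trait value: {bad}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.accession_ids, columns=self.traits
        )


@dataclass
class FilterReport:
    """Accounting of a :func:`filter_matrix` pass."""

    n_markers_in: int
    n_markers_out: int
    n_samples_in: int
    n_samples_out: int
    removed_markers: dict[str, str] = field(default_factory=dict)  # id -> reason
    removed_samples: dict[str, str] = field(default_factory=dict)
    maf_threshold: float = 0.03
    missing_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.n_markers_in - len(self.removed_markers) != self.n_markers_out:
            raise ValidationError("marker counts inconsistent in FilterReport")
        if self.n_samples_in - len(self.removed_samples) != self.n_samples_out:
            raise ValidationError("sample counts inconsistent in FilterReport")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# readers / writers


def read_dosage_tsv(path: str | Path) -> DosageMatrix:
    """Read a dosage matrix from TSV (header = marker ids, col 1 = sample id)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise GenotypeParseError(f"{path}: header has no marker columns")
        marker_ids = header[1:]
        sample_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            sample_ids.append(parts[0])
            row = []
            for m, cell in zip(marker_ids, parts[1:]):
                if cell == _MISSING_TOKEN:
                    row.append(MISSING)
                    continue
                try:
                    v = int(cell)
                except ValueError:
                    raise GenotypeParseError(
                        f"{path}:{lineno}: non-integer call {cell!r} "
                        f"(sample {parts[0]!r}, marker {m!r})"
                    ) from None
                if not 0 <= v <= 4:
                    raise GenotypeParseError(
                        f"{path}:{lineno}: dosage {v} out of range 0..4 "
                        f"(sample {parts[0]!r}, marker {m!r})"
                    )
                row.append(v)
            rows.append(row)
    mat = DosageMatrix(sample_ids, marker_ids, np.array(rows, dtype=np.int8))
    logger.info("read %d samples x %d markers from %s", mat.n_samples, mat.n_markers, path)
    return mat


def write_dosage_tsv(matrix: DosageMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\t" + "\t".join(matrix.marker_ids) + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.calls):
            cells = [_MISSING_TOKEN if v == MISSING else str(int(v)) for v in row]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_dosage_vcf(path: str | Path) -> DosageMatrix:
    """Read dosages from a VCF: dosage = number of ALT alleles in the GT.

    Biallelic sites only; multiallelic records are skipped with a warning.
    A genotype with any missing allele is recorded as :data:`MISSING`.
    """
    import pysam

    path = str(path)
    n_multi = 0
    marker_ids: list[str] = []
    cols: list[np.ndarray] = []
    with pysam.VariantFile(path) as vf:
        sample_ids = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                n_multi += 1
                continue
            marker_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            col = np.empty(len(sample_ids), dtype=np.int8)
            for j, s in enumerate(sample_ids):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    col[j] = MISSING
                else:
                    col[j] = sum(1 for a in gt if a == 1)
            cols.append(col)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic site(s) in {path}")
    calls = (
        np.column_stack(cols) if cols else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return DosageMatrix(sample_ids, marker_ids, calls)


def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read sample metadata from CSV with a ``sample_id`` column."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    out = []
    for _, row in df.iterrows():

        def _get(col, cast):
            v = row.get(col)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            return cast(v)

        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                taxon_label=str(row.get("taxon_label", "unknown")),
                origin=str(row.get("origin", "unknown")),
                replicate_group=_get("replicate_group", str),
                chromosome_count=_get("chromosome_count", int),
                chloroplast_count=_get("chloroplast_count", float),
            )
        )
    return out


def write_sample_metadata(meta: list[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame([m.__dict__ for m in meta]).to_csv(path, index=False)


def read_phenotypes(
    path: str | Path, traits: Sequence[str] = ("ATW", "NTP", "TTY")
) -> PhenotypeTable:
    """Read a phenotype CSV with header ``accession_id,ATW,NTP,TTY``."""
    df = pd.read_csv(path, dtype={"accession_id": str})
    missing_cols = [t for t in traits if t not in df.columns]
    if missing_cols:
        raise GenotypeParseError(f"{path}: missing trait columns {missing_cols}")
    keep = ~df[list(traits)].isna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} phenotype row(s) with no trait value")
    df = df[keep]
    return PhenotypeTable(
        accession_ids=df["accession_id"].tolist(),
        traits=list(traits),
        values=df[list(traits)].to_numpy(dtype=float),
    )


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    df = pheno.to_frame().reset_index(names="accession_id")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# per-marker statistics and filtering


def allele_frequency(matrix: DosageMatrix, marker: str | int) -> float:
    """Alternate-allele frequency p = sum(dosage) / (4 * n non-missing)."""
    j = matrix.marker_ids.index(marker) if isinstance(marker, str) else marker
    col = matrix.calls[:, j]
    ok = col != MISSING
    if not ok.any():
        raise ValidationError(
            f"marker {matrix.marker_ids[j]!r} has no non-missing calls"
        )
    return float(col[ok].sum()) / (4.0 * int(ok.sum()))


def allele_frequencies(matrix: DosageMatrix) -> np.ndarray:
    """Vector of per-marker ALT frequencies (NaN for all-missing markers)."""
    calls = matrix.calls.astype(float)
    calls[matrix.missing_mask()] = np.nan
    n_ok = np.sum(~np.isnan(calls), axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(calls, axis=0) / (4.0 * n_ok)
    p[n_ok == 0] = np.nan
    return p


def minor_allele_frequencies(matrix: DosageMatrix) -> np.ndarray:
    p = allele_frequencies(matrix)
    return np.minimum(p, 1.0 - p)


def marker_missing_fraction(matrix: DosageMatrix) -> np.ndarray:
    return matrix.missing_mask().mean(axis=0)


def sample_missing_fraction(matrix: DosageMatrix) -> np.ndarray:
    return matrix.missing_mask().mean(axis=1)


def filter_matrix(
    matrix: DosageMatrix,
    maf_min: float = 0.03,
    missing_max: float = 0.05,
) -> tuple[DosageMatrix, FilterReport]:
    """Remove low-MAF / high-missingness markers, then high-missingness samples.

    Each pass removes markers first (MAF < ``maf_min`` or missing fraction >
    ``missing_max``), then samples whose missing fraction over the retained
    markers exceeds ``missing_max``.  Because a removal on one axis can shift
    statistics on the other, passes repeat until nothing more is removed, so
    the result is a fixed point: every retained marker and sample satisfies
    the thresholds under recomputation, and the operation is idempotent.
    """
    if matrix.n_samples == 0 or matrix.n_markers == 0:
        raise ValidationError("cannot filter an empty matrix")

    removed_markers: dict[str, str] = {}
    removed_samples: dict[str, str] = {}
    out = matrix
    while True:
        changed = False

        maf = minor_allele_frequencies(out)
        m_miss = marker_missing_fraction(out)
        for j, mid in enumerate(out.marker_ids):
            if m_miss[j] > missing_max:
                removed_markers[mid] = "high_missing"
            elif np.isnan(maf[j]) or maf[j] < maf_min:
                removed_markers[mid] = "low_maf"
        keep_markers = [m for m in out.marker_ids if m not in removed_markers]
        if not keep_markers:
            raise ValidationError("all markers removed by filtering")
        if len(keep_markers) < out.n_markers:
            out = out.subset_markers(keep_markers)
            changed = True

        s_miss = sample_missing_fraction(out)
        for sid, f in zip(out.sample_ids, s_miss):
            if f > missing_max:
                removed_samples[sid] = "high_missing"
        keep_samples = [s for s in out.sample_ids if s not in removed_samples]
        if not keep_samples:
            raise ValidationError("all samples removed by filtering")
        if len(keep_samples) < out.n_samples:
            out = out.subset_samples(keep_samples)
            changed = True

        if not changed:
            break

    report = FilterReport(
        n_markers_in=matrix.n_markers,
        n_markers_out=out.n_markers,
        n_samples_in=matrix.n_samples,
        n_samples_out=out.n_samples,
        removed_markers=removed_markers,
        removed_samples=removed_samples,
        maf_threshold=maf_min,
        missing_threshold=missing_max,
    )
    logger.info(
        "filter: %d->%d markers, %d->%d samples",
        report.n_markers_in,
        report.n_markers_out,
        report.n_samples_in,
        report.n_samples_out,
    )
    return out, report
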