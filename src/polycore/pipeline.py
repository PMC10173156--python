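"""Full-analysis orchestration: filter -> ploidy -> structure -> diversity ->
core selection -> phenotypic validation, driven by a single YAML config."""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, core_select, diversity, geno_io, pheno_validate, ploidy, structure

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed by stage-name hashing."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % 2**32


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "polycore_out"
    dosage_tsv: Optional[str] = None
    dosage_vcf: Optional[str] = None
    metadata_csv: Optional[str] = None
    phenotype_csv: Optional[str] = None
    maf_min: float = 0.03
    missing_max: float = 0.05
    dip_max: float = 0.15
    tet_min: float = 0.20
    k_min: int = 2
    k_max: int = 10
    pca_components: int = 10
    core_fractions: tuple[float, ...] = (0.03, 0.10, 0.15, 0.20)
    n_restarts: int = 20
    n_permutations: int = 999

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise PipelineError("seed must be an integer")
        for f in self.core_fractions:
            if not 0.0 < f <= 1.0:
                raise PipelineError(f"core fraction {f} outside (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        version = raw.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise PipelineError(f"unsupported schema_version {version}")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "core_fractions" in raw:
            raw["core_fractions"] = tuple(raw["core_fractions"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["core_fractions"] = list(self.core_fractions)
        d["schema_version"] = SCHEMA_VERSION
        return d


@dataclass
class RunResult:
    """In-memory handles to every stage product plus the JSON-able report."""

    report: dict
    matrix: geno_io.DosageMatrix
    metadata: list[geno_io.SampleMetadata]
    ploidy_calls: list[ploidy.PloidyCall]
    pca: structure.PcaResult
    groups: structure.GroupAssignment
    mrd: diversity.DistanceMatrix
    ho: diversity.HoResult
    selections: dict[float, core_select.CoreSelection] = field(default_factory=dict)
    phenotypes: Optional[geno_io.PhenotypeTable] = None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> RunResult:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "polycore_version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }

    # ---- load ------------------------------------------------------------
    @_stage("load")
    def _load():
        if config.dosage_tsv:
            m = geno_io.read_dosage_tsv(config.dosage_tsv)
        elif config.dosage_vcf:
            m = geno_io.read_dosage_vcf(config.dosage_vcf)
        else:
            raise PipelineError("no dosage input configured")
        meta = (
            geno_io.read_sample_metadata(config.metadata_csv)
            if config.metadata_csv
            else [geno_io.SampleMetadata(sample_id=s) for s in m.sample_ids]
        )
        phe = geno_io.read_phenotypes(config.phenotype_csv) if config.phenotype_csv else None
        return m, meta, phe

    matrix, metadata, phenotypes = _load()
    report["stages"]["load"] = {
        "n_samples": matrix.n_samples,
        "n_markers": matrix.n_markers,
        "has_metadata": config.metadata_csv is not None,
        "has_phenotypes": phenotypes is not None,
    }

    # ---- filter ----------------------------------------------------------
    @_stage("filter")
    def _filter():
        return geno_io.filter_matrix(matrix, config.maf_min, config.missing_max)

    matrix, filter_report = _filter()
    filter_report.to_json(out_dir / "filter_report.json")
    geno_io.write_dosage_tsv(matrix, out_dir / "filtered_matrix.tsv")
    report["stages"]["filter"] = {
        "n_markers_retained": filter_report.n_markers_out,
        "n_samples_retained": filter_report.n_samples_out,
        "n_markers_removed": len(filter_report.removed_markers),
        "n_samples_removed": len(filter_report.removed_samples),
    }

    # ---- ploidy ----------------------------------------------------------
    @_stage("ploidy")
    def _ploidy():
        calls = ploidy.call_ploidy(matrix, config.dip_max, config.tet_min)
        pd.DataFrame(
            {
                "sample_id": [c.sample_id for c in calls],
                "st_freq": [round(c.st_freq, 4) for c in calls],
                "call": [c.call for c in calls],
            }
        ).to_csv(out_dir / "ploidy.tsv", sep="\t", index=False)
        return calls

    ploidy_calls = _ploidy()
    counts = pd.Series([c.call for c in ploidy_calls]).value_counts().to_dict()
    stage: dict[str, Any] = {"calls": counts, "thresholds": [config.dip_max, config.tet_min]}
    reference = [m for m in metadata if ploidy.reference_class(m) is not None]
    if reference:
        rep = ploidy.concordance(ploidy_calls, reference)
        stage["concordance"] = {
            cls: {
                "n_reference": s.n_reference,
                "n_correct": s.n_correct,
                "accuracy_pct": s.accuracy_pct,
            }
            for cls, s in rep.per_class.items()
        }
    rep_checks = ploidy.replicate_consistency(ploidy_calls, metadata)
    if rep_checks:
        stage["replicates"] = {
            "n_groups": len(rep_checks),
            "n_consistent": sum(r.consistent for r in rep_checks),
        }
    report["stages"]["ploidy"] = stage

    # ---- structure -------------------------------------------------------
    @_stage("structure")
    def _structure():
        pca_res = structure.pca(matrix, n_components=config.pca_components)
        k_max = min(config.k_max, matrix.n_samples - 1)
        groups_res = structure.choose_k(
            pca_res.scores,
            k_min=config.k_min,
            k_max=k_max,
            seed=stage_seed(config.seed, "structure"),
        )
        pd.DataFrame(
            pca_res.scores,
            index=pca_res.sample_ids,
            columns=[f"PC{i + 1}" for i in range(pca_res.scores.shape[1])],
        ).to_csv(out_dir / "pca_scores.tsv", sep="\t", index_label="sample_id")
        pd.DataFrame(
            {"sample_id": pca_res.sample_ids, "group": groups_res.labels}
        ).to_csv(out_dir / "groups.tsv", sep="\t", index=False)
        return pca_res, groups_res

    pca_res, groups_res = _structure()
    report["stages"]["structure"] = {
        "percent_variance": [round(float(v), 2) for v in pca_res.percent_variance[:5]],
        "chosen_k": groups_res.k,
        "low_confidence": groups_res.low_confidence,
    }

    # ---- diversity -------------------------------------------------------
    group_labels = [f"G{g + 1}" for g in groups_res.labels]

    @_stage("diversity")
    def _diversity():
        ho = diversity.observed_heterozygosity(matrix, group_labels)
        mrd = diversity.mrd_matrix(matrix)
        mrd.to_tsv(out_dir / "mrd.tsv")
        amova_res = diversity.amova(
            mrd,
            group_labels,
            n_perm=config.n_permutations,
            seed=stage_seed(config.seed, "amova"),
        )
        fst_res = diversity.nei_fst(
            matrix,
            group_labels,
            n_perm=min(config.n_permutations, 199),
            seed=stage_seed(config.seed, "fst"),
        )
        return ho, mrd, amova_res, fst_res

    ho, mrd, amova_res, fst_res = _diversity()
    report["stages"]["diversity"] = {
        "ho_mean": round(ho.mean(), 4),
        "ho_sd": round(ho.sd(), 4),
        "ho_by_group": {g: [round(m, 4), round(s, 4)] for g, (m, s) in ho.group_means.items()},
        "amova": {
            "phi": round(amova_res.phi, 4),
            "pct_among": round(amova_res.pct_among, 2),
            "pct_within": round(amova_res.pct_within, 2),
            "p_value": amova_res.p_value,
        },
        "fst": {f"{a}|{b}": round(v, 4) for (a, b), v in fst_res.fst.items()},
    }

    # ---- core selection --------------------------------------------------
    @_stage("core")
    def _core():
        selections: dict[float, core_select.CoreSelection] = {}
        for frac in config.core_fractions:
            k = core_select.core_size(matrix.n_samples, frac)
            sel = core_select.select_core(
                mrd,
                k,
                seed=stage_seed(config.seed, f"core_{frac}"),
                n_restarts=config.n_restarts,
            )
            sel.fraction = frac
            selections[frac] = sel
        if 0.03 in selections and 0.10 in selections:
            nested = core_select.nest_minicore(
                selections[0.03].entry_ids, selections[0.10].entry_ids, mrd
            )
            selections[0.03] = core_select.CoreSelection(
                entry_ids=nested,
                fraction=0.03,
                objective_values={
                    "A_NE": core_select.ane_objective(mrd, nested),
                    "E_NE": core_select.ene_objective(mrd, nested),
                    "E_E": core_select.ee_objective(mrd, nested),
                },
                optimizer_trace={"nested_into": 0.10},
            )
        return selections

    selections = _core()
    eval_table = core_select.evaluate_cores(mrd, selections)
    eval_table.to_csv(out_dir / "core_evaluation.tsv", sep="\t", index=False)
    with (out_dir / "cores.json").open("w") as fh:
        json.dump(
            {
                str(f): {
                    "entry_ids": s.entry_ids,
                    "objectives": s.objective_values,
                }
                for f, s in selections.items()
            },
            fh,
            indent=2,
        )
    report["stages"]["core"] = {
        str(f): {
            "n_entries": len(s.entry_ids),
            **{k: round(v, 4) for k, v in s.objective_values.items()},
        }
        for f, s in selections.items()
    }

    # ---- Ho comparison across collections --------------------------------
    collections = {"whole": list(matrix.sample_ids)}
    collections.update({f"core_{f}": s.entry_ids for f, s in selections.items()})
    ho_table = compare_collections(ho, collections, group_labels)
    ho_table.to_csv(out_dir / "ho_comparison.tsv", sep="\t", index=False)
    report["stages"]["ho_comparison"] = {
        r["collection"]: [round(r["ho_mean"], 4), round(r["ho_sd"], 4)]
        for _, r in ho_table[ho_table["group"] == "all"].iterrows()
    }

    # ---- phenotypic validation ------------------------------------------
    if phenotypes is not None:

        @_stage("pheno")
        def _pheno():
            gower = pheno_validate.gower_distance(phenotypes)
            metrics = pheno_validate.evaluate_cores_pheno(gower, selections)
            stats = pheno_validate.summary_stats(
                phenotypes,
                {
                    name: [a for a in entries if a in phenotypes.accession_ids]
                    for name, entries in collections.items()
                },
            )
            return gower, metrics, stats

        gower, metrics, stats = _pheno()
        metrics.to_csv(out_dir / "pheno_core_metrics.tsv", sep="\t", index=False)
        stats.to_csv(out_dir / "pheno_summary.tsv", sep="\t", index=False)
        report["stages"]["pheno"] = {
            "n_phenotyped": len(phenotypes.accession_ids),
            "metrics": metrics.round(4).to_dict(orient="records"),
        }

    with (out_dir / "run_report.json").open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete; report at %s", out_dir / "run_report.json")
    return RunResult(
        report=report,
        matrix=matrix,
        metadata=metadata,
        ploidy_calls=ploidy_calls,
        pca=pca_res,
        groups=groups_res,
        mrd=mrd,
        ho=ho,
        selections=selections,
        phenotypes=phenotypes,
    )


def compare_collections(
    ho: diversity.HoResult,
    collections: Mapping[str, Sequence[str]],
    group_labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Mean +/- sd Ho per collection, overall and per genetic group."""
    ho_by_id = dict(zip(ho.sample_ids, ho.ho))
    label_by_id = (
        dict(zip(ho.sample_ids, group_labels)) if group_labels is not None else {}
    )
    rows = []
    for name, entries in collections.items():
        vals = np.array([ho_by_id[e] for e in entries if e in ho_by_id])
        if vals.size == 0:
            continue
        rows.append(
            {
                "collection": name,
                "group": "all",
                "n": int(vals.size),
                "ho_mean": float(vals.mean()),
                "ho_sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            }
        )
        if label_by_id:
            labs = np.array([label_by_id[e] for e in entries if e in ho_by_id])
            for g in sorted(set(labs.tolist())):
                gv = vals[labs == g]
                rows.append(
                    {
                        "collection": name,
                        "group": g,
                        "n": int(gv.size),
                        "ho_mean": float(gv.mean()),
                        "ho_sd": float(gv.std(ddof=1)) if gv.size > 1 else 0.0,
                    }
                )
    return pd.DataFrame(rows)
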