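"""End-to-end orchestration: ingest → descriptors → clustering → statistics.

``run`` executes the whole comparison on one pair of labeled ligand sets:
curation, descriptor computation, two-level redundancy clustering at every
requested level, cluster-weighted (and optionally center-based) comparison of
every descriptor, the four-level robustness verdict, the cross-set
chemical-overlap count, and report assembly.  Every stage is a pure function
of (inputs, config, seed); the JSON summary is byte-identical across reruns
of the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import chemspace, ingest
from .descriptors import ANALYZED_CODES, descriptor_table
from .ingest import AssayRecord, LigandRecord, ProteinRecord
from .redundancy import (
    LEVELS,
    ClusteringLevel,
    IdentityCache,
    LigandCluster,
    ProteinFamily,
    build_protein_ligand_clusters,
)
from .weighted_stats import (
    DEFAULT_BOOTSTRAP_SAMPLES,
    ComparisonResult,
    compare_descriptor,
    robust_verdict,
    set_vectors,
    single_level_analysis,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "PipelineError", "run"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run.

    ``ligands``/``proteins``/``assays`` may be paths (CSV/TSV/XLSX, FASTA) or
    in-memory objects in the ingest module's formats.
    """

    ligands: object
    proteins: object
    assays: object | None = None
    apply_assay_filter: bool = False
    curation_blacklist: tuple[str, ...] = ()
    panel_max_targets: int = ingest.DEFAULT_MAX_TARGETS
    levels: tuple[ClusteringLevel, ...] = LEVELS
    schemes: tuple[str, ...] = ("weighted",)
    codes: tuple[str, ...] = ANALYZED_CODES
    single_level: bool = False
    single_level_thresholds: tuple[float, ...] = (0.6, 0.75, 0.9, 1.0)
    overlap_tc: float = 0.6
    n_boot: int = DEFAULT_BOOTSTRAP_SAMPLES
    bootstrap_sample_size: int | None = None
    ci_mode: str = "always"
    seed: int = 0
    out_dir: str | None = None


@dataclass
class RunReport:
    """Everything a run produced: the canonical JSON summary plus tables."""

    summary: dict
    comparisons: pd.DataFrame
    verdicts: pd.DataFrame
    table1: pd.DataFrame
    descriptors: dict[str, pd.DataFrame]
    clusters: dict[str, dict[str, list[LigandCluster]]]
    families: dict[str, dict[str, list[ProteinFamily]]]
    scatter: pd.DataFrame
    single_level: dict | None = None


def _config_hash(config: RunConfig) -> str:
    def token(x):
        if isinstance(x, pd.DataFrame):
            return int(pd.util.hash_pandas_object(x, index=False).sum())
        if isinstance(x, (list, tuple)):
            return [token(i) for i in x]
        if isinstance(x, (ProteinRecord, ClusteringLevel)):
            return repr(x)
        if isinstance(x, (str, int, float, bool)) or x is None:
            return x
        return repr(x)

    payload = {k: token(v) for k, v in vars(config).items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_inputs(
    config: RunConfig,
) -> tuple[list[LigandRecord], list[ProteinRecord], list[AssayRecord] | None]:
    ligands = ingest.read_ligand_table(config.ligands)
    if isinstance(config.proteins, (str, Path)):
        proteins = ingest.read_fasta(config.proteins)
    else:
        proteins = list(config.proteins)
    assays = None
    if config.assays is not None:
        assays = ingest.read_assay_table(config.assays)
    return ligands, proteins, assays


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, exc) from exc
            logger.info("stage %-12s %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run(config: RunConfig) -> RunReport:
    """Execute the full comparison pipeline for one configuration."""
    ligands, proteins, assays = _stage("load")(_load_inputs)(config)

    @_stage("curate")
    def _curate():
        out: dict[str, ingest.CurationReport] = {}
        for label in ingest.SET_LABELS:
            subset = [r for r in ligands if r.set_label == label]
            out[label] = ingest.curate(
                subset,
                assays=assays if config.apply_assay_filter else None,
                mode=label if config.apply_assay_filter else None,
                curation_blacklist=config.curation_blacklist,
                max_targets=config.panel_max_targets,
            )
        return out

    curated = _curate()

    @_stage("descriptors")
    def _descriptors():
        tables: dict[str, pd.DataFrame] = {}
        fps: dict[str, list[chemspace.Fingerprint]] = {}
        for label, rep in curated.items():
            ids = [r.ligand_id for r in rep.records]
            smiles = [r.smiles_canonical for r in rep.records]
            tables[label] = descriptor_table(smiles, index=ids)
            fps[label] = [
                chemspace.ecfp6(s, ligand_id=i) for i, s in zip(ids, smiles)
            ]
        return tables, fps

    desc, fps = _descriptors()

    @_stage("clustering")
    def _clustering():
        families: dict[str, dict[str, list[ProteinFamily]]] = {}
        clusters: dict[str, dict[str, list[LigandCluster]]] = {}
        protein_by_id = {p.protein_id: p for p in proteins}
        for label, rep in curated.items():
            target_ids = {t for r in rep.records for t in r.target_ids}
            set_proteins = [protein_by_id[t] for t in sorted(target_ids) if t in protein_by_id]
            cache = IdentityCache()
            fp_map = {f.ligand_id: f for f in fps[label]}
            ha = desc[label]["a_heavy"].astype(int).to_dict()
            families[label] = {}
            clusters[label] = {}
            for level in config.levels:
                fams, cls = build_protein_ligand_clusters(
                    rep.records, set_proteins, level,
                    fingerprints=fp_map, identity=cache, heavy_atom_counts=ha,
                )
                families[label][level.label] = fams
                clusters[label][level.label] = cls
        return families, clusters

    families, clusters = _clustering()

    @_stage("compare")
    def _compare():
        results: dict[str, dict[str, dict[str, ComparisonResult]]] = {}
        for scheme in config.schemes:
            results[scheme] = {}
            for code in config.codes:
                per_level: dict[str, ComparisonResult] = {}
                for level in config.levels:
                    sv = {
                        label: set_vectors(
                            clusters[label][level.label], desc[label][code].to_dict()
                        )
                        for label in ingest.SET_LABELS
                    }
                    per_level[level.label] = compare_descriptor(
                        code,
                        sv["allosteric"],
                        sv["competitive"],
                        level_label=level.label,
                        scheme=scheme,
                        n_boot=config.n_boot,
                        sample_size=config.bootstrap_sample_size,
                        seed=config.seed,
                        ci_mode=config.ci_mode,
                    )
                results[scheme][code] = per_level
        return results

    comparisons = _compare()

    @_stage("verdicts")
    def _verdicts():
        out = {}
        if len(config.levels) == 4:
            for scheme, by_code in comparisons.items():
                out[scheme] = {
                    code: robust_verdict(list(per_level.values()))
                    for code, per_level in by_code.items()
                }
        return out

    verdicts = _verdicts()

    @_stage("overlap")
    def _overlap():
        if not fps["allosteric"] or not fps["competitive"]:
            return None
        a, c = chemspace.cross_set_neighbor_count(
            fps["allosteric"], fps["competitive"], config.overlap_tc
        )
        return {
            "tc_threshold": config.overlap_tc,
            "allosteric_near_competitive": a,
            "total_allosteric": len(fps["allosteric"]),
            "competitive_near_allosteric": c,
            "total_competitive": len(fps["competitive"]),
        }

    overlap = _overlap()

    single = None
    if config.single_level:
        @_stage("single_level")
        def _single():
            return single_level_analysis(
                fps["allosteric"], desc["allosteric"],
                fps["competitive"], desc["competitive"],
                tc_thresholds=config.single_level_thresholds,
                codes=config.codes,
                n_boot=config.n_boot,
                seed=config.seed,
                ci_mode=config.ci_mode,
            )
        single = _single()

    report = _stage("report")(_assemble_report)(
        config, curated, desc, fps, families, clusters, comparisons, verdicts,
        overlap, single,
    )
    if config.out_dir is not None:
        _stage("write")(_write_outputs)(report, config)
    return report


# --------------------------------------------------------------------------
# report assembly
# --------------------------------------------------------------------------

def _comparison_rows(comparisons) -> pd.DataFrame:
    rows = []
    for scheme, by_code in comparisons.items():
        for code, per_level in by_code.items():
            for label, r in per_level.items():
                rows.append(
                    {
                        "scheme": scheme,
                        "descriptor": code,
                        "level": label,
                        "median_allo": r.median_allo,
                        "median_comp": r.median_comp,
                        "ci_allo_lo": None if r.ci95_allo is None else r.ci95_allo[0],
                        "ci_allo_hi": None if r.ci95_allo is None else r.ci95_allo[1],
                        "ci_comp_lo": None if r.ci95_comp is None else r.ci95_comp[0],
                        "ci_comp_hi": None if r.ci95_comp is None else r.ci95_comp[1],
                        "p_value": r.p_value,
                        "significant": r.significant_at_level,
                        "direction": r.direction,
                    }
                )
    return pd.DataFrame(rows)


def _assemble_report(
    config, curated, desc, fps, families, clusters, comparisons, verdicts,
    overlap, single,
) -> RunReport:
    table1_rows = []
    for label in ingest.SET_LABELS:
        row = {
            "set": label,
            "unique_ligands": len(curated[label].records),
            "unique_proteins": len(
                {t for r in curated[label].records for t in r.target_ids}
            ),
        }
        for level_label, fams in families[label].items():
            fams_with_ligands = {c.family_id for c in clusters[label][level_label]}
            row[f"families_{level_label}"] = len(fams_with_ligands)
            row[f"clusters_{level_label}"] = len(clusters[label][level_label])
        table1_rows.append(row)
    table1 = pd.DataFrame(table1_rows)

    scatter = pd.concat(
        [
            desc[label][["a_heavy", "SlogP"]].assign(set=label)
            for label in ingest.SET_LABELS
        ]
    ).rename_axis("ligand_id").reset_index()

    summary = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "curation": {
            label: {
                "n_input": rep.n_input,
                "n_unique_ligands": len(rep.records),
                "n_rejected": len(rep.rejected),
                "n_duplicates_removed": rep.n_duplicates_removed,
                "n_assay_filtered": rep.n_assay_filtered,
                "panel_flagged": rep.panel_flagged,
            }
            for label, rep in curated.items()
        },
        "counts": table1.to_dict(orient="records"),
        "comparisons": {
            scheme: {
                code: {
                    label: {
                        "median_allo": r.median_allo,
                        "median_comp": r.median_comp,
                        "ci95_allo": r.ci95_allo,
                        "ci95_comp": r.ci95_comp,
                        "p_value": r.p_value,
                        "significant": r.significant_at_level,
                        "direction": r.direction,
                    }
                    for label, r in per_level.items()
                }
                for code, per_level in by_code.items()
            }
            for scheme, by_code in comparisons.items()
        },
        "robust_verdicts": {
            scheme: {
                code: {"significant_all_levels": v.significant_all_levels, "direction": v.direction}
                for code, v in by_code.items()
            }
            for scheme, by_code in verdicts.items()
        },
        "overlap": overlap,
    }
    if single is not None:
        summary["single_level"] = {
            f"tc{tc:g}": {
                code: {
                    "median_allo": r.median_allo,
                    "median_comp": r.median_comp,
                    "p_value": r.p_value,
                    "significant": r.significant_at_level,
                    "direction": r.direction,
                }
                for code, r in per_code.items()
            }
            for tc, per_code in single.items()
        }

    verdict_rows = [
        {
            "scheme": scheme,
            "descriptor": code,
            "significant_all_levels": v.significant_all_levels,
            "direction": v.direction,
        }
        for scheme, by_code in verdicts.items()
        for code, v in by_code.items()
    ]
    return RunReport(
        summary=summary,
        comparisons=_comparison_rows(comparisons),
        verdicts=pd.DataFrame(verdict_rows),
        table1=table1,
        descriptors=desc,
        clusters=clusters,
        families=families,
        scatter=scatter,
        single_level=single,
    )


def _write_outputs(report: RunReport, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=1, sort_keys=True)
    report.comparisons.to_csv(out / "comparisons.csv", index=False)
    report.verdicts.to_csv(out / "verdicts.csv", index=False)
    report.table1.to_csv(out / "set_counts.csv", index=False)
    report.scatter.to_csv(out / "slogp_vs_ha.csv", index=False)
    for label, df in report.descriptors.items():
        safe = df.rename(columns=lambda c: c.replace("/HA", "_per_HA"))
        safe.rename_axis("ligand_id").to_csv(out / f"descriptors_{label}.csv")
    cluster_rows = []
    for label, by_level in report.clusters.items():
        for level_label, cls in by_level.items():
            for cl in cls:
                for lid in cl.member_ligand_ids:
                    cluster_rows.append(
                        {
                            "set": label,
                            "level": level_label,
                            "family_id": cl.family_id,
                            "cluster_id": cl.cluster_id,
                            "ligand_id": lid,
                            "is_center": lid == cl.center_ligand_id,
                        }
                    )
    pd.DataFrame(cluster_rows).to_csv(out / "clusters.csv", index=False)
    family_rows = [
        {"set": label, "level": level_label, "family_id": f.family_id, "protein_id": pid}
        for label, by_level in report.families.items()
        for level_label, fams in by_level.items()
        for f in fams
        for pid in f.member_protein_ids
    ]
    pd.DataFrame(family_rows).to_csv(out / "families.csv", index=False)
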