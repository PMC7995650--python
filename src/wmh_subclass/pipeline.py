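"""Per-subject pipeline composition and provenance.

``run_subject`` chains the stages (intensity split, cluster labeling,
location classification, sub-class combination, rim/core decomposition,
volumetrics, optional DTI summaries) on an in-memory bundle;
``run_all`` is the file-level wrapper that loads inputs, runs the
pipeline, and writes every output with a provenance sidecar (parameters,
package version, input checksums).  Composition is deterministic:
running the stages individually yields byte-identical numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .cluster_decompose import ClusterRecord, DecompositionSummary, decompose
from .config import RunConfig
from .intensity_classify import IntensitySplit, split_by_pve
from .location_classify import (
    ClusterLabeling,
    SubclassMap,
    classify_location,
    combine_subclasses,
    label_clusters,
)
from .stats_models import run_model_family
from .volumes_io import (
    BinaryMask,
    CohortSchema,
    SubjectBundle,
    VoxelGrid,
    assert_same_grid,
    binarize,
    load_cohort_table,
    load_mask,
    load_volume,
    save_volume,
)
from .volumetrics_dti import DtiSummary, VolumeReport, compute_volumes, summarize_dti

__all__ = ["SubjectResult", "run_subject", "run_all", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage (and subject, if known)."""


@dataclass
class SubjectResult:
    split: IntensitySplit
    clusters: ClusterLabeling
    peri_flags: np.ndarray
    subclass_map: SubclassMap
    cluster_records: list[ClusterRecord]
    decomposition: DecompositionSummary
    volumes: VolumeReport
    dti: dict[str, dict[str, DtiSummary]] | None  # metric -> {hypo, nonhypo}


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc


def run_subject(bundle: SubjectBundle, config: RunConfig | None = None) -> SubjectResult:
    """Run the full sub-classification pipeline on one subject bundle."""
    config = (config or RunConfig()).validate()
    _stage("grid-check", assert_same_grid, bundle)

    wmh = bundle.wmh
    if isinstance(wmh, VoxelGrid):  # probability map: threshold first
        wmh = _stage(
            "binarize",
            binarize,
            wmh,
            threshold=config.wmh_probability_threshold,
            strict=config.wmh_threshold_strict,
        )
    assert isinstance(wmh, BinaryMask)

    split = _stage("intensity", split_by_pve, wmh, bundle.wm_pve, config.pve_threshold)
    clusters = _stage("clustering", label_clusters, wmh, config.connectivity)
    peri_flags = _stage("location", classify_location, clusters, bundle.ventricle_ext)
    smap = _stage("combine", combine_subclasses, clusters, peri_flags, split)
    records, summary = _stage("decompose", decompose, clusters, split, peri_flags)
    volumes = _stage(
        "volumes",
        compute_volumes,
        smap,
        brain_volume_dm3=bundle.brain_volume_dm3(),
        log_base=config.log_base,
        zero_policy=config.zero_policy,
    )
    dti = None
    if bundle.dti:
        dti = {}
        for metric, grid in bundle.dti.items():
            dti[metric] = {
                "hypo": _stage("dti", summarize_dti, split.hypo, grid),
                "nonhypo": _stage("dti", summarize_dti, split.non_hypo, grid),
            }
    return SubjectResult(
        split=split,
        clusters=clusters,
        peri_flags=peri_flags,
        subclass_map=smap,
        cluster_records=records,
        decomposition=summary,
        volumes=volumes,
        dti=dti,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_bundle(config: RunConfig) -> SubjectBundle:
    """Build a SubjectBundle from the paths in a config."""
    if not config.wmh_path or not config.pve_path or not config.ventricle_path:
        raise PipelineError("config must set wmh_path, pve_path and ventricle_path")
    wmh_grid = load_volume(config.wmh_path)
    # pre-binarised masks pass through load_mask semantics; probability maps
    # are kept as grids and thresholded inside run_subject
    wmh_vals = np.unique(wmh_grid.data)
    wmh: BinaryMask | VoxelGrid
    if np.isin(wmh_vals, (0, 1)).all():
        wmh = BinaryMask(wmh_grid.with_data(wmh_grid.data.astype(np.uint8)))
    else:
        wmh = wmh_grid
    return SubjectBundle(
        wmh=wmh,
        wm_pve=load_volume(config.pve_path),
        ventricle_ext=load_mask(config.ventricle_path),
        brain=load_mask(config.brain_path) if config.brain_path else None,
        total_brain_volume_dm3=config.brain_volume_dm3,
        dti={k: load_volume(v) for k, v in config.dti_paths.items()} or None,
    )


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """File-level pipeline: load, run, write outputs + provenance JSON.

    Returns the summary dictionary that was written to ``summary.json``.
    """
    config = config.validate()
    out = Path(out_dir or config.out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)

    bundle = _stage("load", load_bundle, config)
    result = run_subject(bundle, config)

    save_volume(
        result.subclass_map.grid.with_data(result.subclass_map.labels),
        out / "subclass_map.nii.gz",
    )
    save_volume(
        result.clusters.grid.with_data(result.clusters.labels.astype(np.int32)),
        out / "clusters.nii.gz",
    )
    for name in ("peri_hypo", "peri_nonhypo", "deep_hypo", "deep_nonhypo"):
        save_volume(result.subclass_map.mask_of(name).grid, out / f"{name}.nii.gz")

    records_csv = out / "cluster_records.csv"
    with records_csv.open("w") as fh:
        fh.write("cluster_id,size_voxels,volume_mm3,has_hypo,core_voxels,rim_voxels,location\n")
        for r in result.cluster_records:
            fh.write(
                f"{r.cluster_id},{r.size_voxels},{r.volume_mm3:.6g},"
                f"{int(r.has_hypo)},{r.core_voxels},{r.rim_voxels},{r.location}\n"
            )

    summary = {
        "volumes": {
            "raw_cm3": result.volumes.raw_cm3,
            "adjusted": result.volumes.adjusted,
            "log_adjusted": {
                k: (None if not np.isfinite(v) else v)
                for k, v in result.volumes.log_adjusted.items()
            },
            "brain_volume_dm3": result.volumes.brain_volume_dm3,
            "log_base": result.volumes.log_base,
            "missing": result.volumes.missing,
        },
        "decomposition": dataclasses.asdict(result.decomposition),
        "n_clusters": result.clusters.n_clusters,
        "subclass_counts": result.subclass_map.counts(),
    }
    if result.dti:
        summary["dti"] = {
            metric: {k: dataclasses.asdict(v) for k, v in masks.items()}
            for metric, masks in result.dti.items()
        }

    stats_out = None
    if config.cohort_path:
        schema = CohortSchema(numeric=(), categorical={})
        table = load_cohort_table(config.cohort_path, schema)
        results = _stage(
            "stats",
            run_model_family,
            table,
            mode=config.stats_mode,
            m_bonferroni=config.bonferroni_m,
            alpha=config.alpha,
        )
        stats_out = {
            outcome: {
                "model_f": res.model_f,
                "model_p": res.model_p,
                "adj_r2": res.adj_r2,
                "n_used": res.n_used,
                "terms": {
                    t: dataclasses.asdict(tr) for t, tr in res.terms.items()
                },
                "p_bonferroni": res.p_bonferroni,
            }
            for outcome, res in results.items()
        }
        summary["stats"] = stats_out

    provenance = {
        "software": "wmh-subclass",
        "version": __version__,
        "parameters": config.to_dict(),
        "inputs": {
            name: _sha256(Path(p))
            for name, p in {
                "wmh": config.wmh_path,
                "pve": config.pve_path,
                "ventricles": config.ventricle_path,
                "brain": config.brain_path,
                "cohort": config.cohort_path,
                **{f"dti:{k}": v for k, v in config.dti_paths.items()},
            }.items()
            if p
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return summary
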