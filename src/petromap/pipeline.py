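"""End-to-end subject and cohort runs with reproducible artifacts.

Every output directory gets a ``manifest.json`` recording the
configuration hash, seed and package version; deterministic stages
reproduce byte-identical artifacts on rerun.  All CSV coordinates are
frame-local millimetres in the right-side convention (left sides are
mirrored); angles are degrees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .geometry import AnatomyFrame, TriangleMesh, to_frame_many
from .thickness import (
    CLTParams,
    GridSpec,
    compute_clt,
    compute_ddvs,
    project_grid_local,
    samples_to_dataframe,
    samples_to_map,
)
from .regions import RegionConfig, region_masks
from .screws import batch_screw_report, report_to_csv, screws_from_csv
from .stats import (
    SubjectMeta,
    aggregate_group_maps,
    build_percentile_table,
    distribution_export,
    distributions_to_csv,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SubjectResult", "run_subject", "run_cohort"]


@dataclass
class RunConfig:
    """Inputs and parameters of one subject analysis."""

    bone_path: str
    dura_path: str
    frame_path: str
    out_dir: str
    subject_id: str = ""
    screws_path: Optional[str] = None
    region_config_path: Optional[str] = None
    grid: GridSpec = field(default_factory=GridSpec)
    clt: CLTParams = field(default_factory=CLTParams)
    seed: int = 0
    log_level: str = "INFO"
    render_png: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = self.grid.to_dict()
        d["clt"] = dataclasses.asdict(self.clt)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "grid" in d and not isinstance(d["grid"], GridSpec):
            d["grid"] = GridSpec.from_dict(d["grid"])
        if "clt" in d and not isinstance(d["clt"], CLTParams):
            d["clt"] = CLTParams(**d["clt"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SubjectResult:
    samples: list
    clt_map: object
    ddvs_map: object
    table: object
    screw_results: Optional[list]
    n_contact: Optional[int]
    artifacts: dict[str, str]


def _stage(name: str, path: str | None = None):
    """Context that renames stage failures with the input path."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(
                    f"stage {name!r} failed"
                    + (f" (input: {path})" if path else "")
                ) from exc
            logger.info("stage %s done in %.2f s", name, time.perf_counter() - self.t0)
            return False
    return _Ctx()


def run_subject(config: RunConfig) -> SubjectResult:
    """Full single-subject analysis: projection, CLT, DDVS, regions,
    maps, percentile table and (optionally) a screw clearance report."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    with _stage("load", config.bone_path):
        bone = TriangleMesh.load(config.bone_path)
        frame = AnatomyFrame.load(config.frame_path)
        bone_local = TriangleMesh(
            to_frame_many(frame, bone.vertices),
            bone.faces[:, ::-1] if frame.side == "left" else bone.faces,
            name=bone.name,
        )
    if config.dura_path is None or not Path(config.dura_path).exists():
        raise FileNotFoundError(
            f"DDVS stage input missing: dura mesh {config.dura_path!r}"
        )
    with _stage("load_dura", config.dura_path):
        dura = TriangleMesh.load(config.dura_path)
        dura_local = TriangleMesh(
            to_frame_many(frame, dura.vertices),
            dura.faces[:, ::-1] if frame.side == "left" else dura.faces,
            name=dura.name,
        )

    with _stage("project", config.bone_path):
        samples = project_grid_local(bone_local, config.grid)
        n_valid = sum(s.valid for s in samples)
        logger.info("projected %d/%d grid nodes", n_valid, len(samples))

    with _stage("clt"):
        compute_clt(samples, bone_local, config.clt)
        n_cens = sum(s.clt_censored for s in samples)
        if n_cens:
            logger.warning("%d CLT values censored at %.1f mm", n_cens,
                           config.clt.max_thickness)

    with _stage("ddvs", config.dura_path):
        compute_ddvs(samples, dura_local)

    with _stage("regions", config.region_config_path):
        region_cfg = (RegionConfig.load(config.region_config_path)
                      if config.region_config_path else RegionConfig())
        region_masks(samples, region_cfg)

    with _stage("tables"):
        table = build_percentile_table(samples)
        table_path = out / "percentiles.csv"
        table.save_csv(table_path)
        artifacts["percentile_table"] = str(table_path)

        df = samples_to_dataframe(samples)
        samples_path = out / "samples.csv"
        header = ("# frame-local mm, right-side convention after mirroring; "
                  "angles in degrees\n")
        with open(samples_path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.9g")
        artifacts["samples"] = str(samples_path)

        records = distribution_export(samples, by="region", metric="CLT")
        dist_path = out / "distributions_clt.csv"
        distributions_to_csv(records, dist_path)
        artifacts["distributions"] = str(dist_path)

    with _stage("maps"):
        clt_map = samples_to_map(samples, "CLT", config.grid, config.subject_id)
        ddvs_map = samples_to_map(samples, "DDVS", config.grid, config.subject_id)
        for m, stem in ((clt_map, "clt_map"), (ddvs_map, "ddvs_map")):
            m.save(out / stem)
            artifacts[stem] = str(out / f"{stem}.csv")
            if config.render_png:
                m.render_png(out / f"{stem}.png")

    screw_results = None
    n_contact = None
    if config.screws_path:
        with _stage("screws", config.screws_path):
            screws = screws_from_csv(config.screws_path)
            # digitized coordinates are in world space: map into the frame
            for s in screws:
                s.head = to_frame_many(frame, s.head[None, :])[0]
                s.tip = to_frame_many(frame, s.tip[None, :])[0]
            screw_results, n_contact = batch_screw_report(screws, dura_local)
            report_path = out / "screw_report.csv"
            report_to_csv(screw_results, report_path)
            artifacts["screw_report"] = str(report_path)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_samples": len(samples),
        "n_valid": int(sum(s.valid for s in samples)),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = str(out / "manifest.json")

    return SubjectResult(samples=samples, clt_map=clt_map, ddvs_map=ddvs_map,
                         table=table, screw_results=screw_results,
                         n_contact=n_contact, artifacts=artifacts)


def run_cohort(configs: Sequence[RunConfig], metas: Sequence[SubjectMeta],
               out_dir: str | Path) -> dict:
    """Per-subject runs plus pooled table, group map aggregation and the
    cohort screw contact count."""
    if len(configs) == 0:
        raise ValueError("need at least one subject")
    if len(metas) != len(configs):
        raise ValueError("need one SubjectMeta per RunConfig")
    ref_grid = configs[0].grid
    for c in configs[1:]:
        if c.grid.to_dict() != ref_grid.to_dict():
            raise ValueError(
                "all subjects must share one GridSpec; set the same grid "
                "spacing and extent in every RunConfig"
            )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    results = [run_subject(c) for c in configs]

    pooled_samples = [s for r in results for s in r.samples]
    pooled_table = build_percentile_table(pooled_samples)
    pooled_table.save_csv(out / "percentiles_pooled.csv")

    clt_maps = [r.clt_map for r in results]
    agg_all = aggregate_group_maps(clt_maps, metas, grouping="all")
    agg_by = aggregate_group_maps(clt_maps, metas, grouping="by_group")
    for key, gset in {**agg_all, **{f"group_{k}": v for k, v in agg_by.items()}}.items():
        gset.mean_map.save(out / f"clt_mean_{key}")
        gset.min_map.save(out / f"clt_min_{key}")

    n_contacts = [r.n_contact for r in results if r.n_contact is not None]
    cohort_contacts = int(sum(n_contacts)) if n_contacts else None

    summary = {
        "n_subjects": len(configs),
        "subjects": [dataclasses.asdict(m) for m in metas],
        "cohort_screw_contacts": cohort_contacts,
        "pooled_table": str(out / "percentiles_pooled.csv"),
    }
    (out / "cohort_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return {
        "results": results,
        "pooled_table": pooled_table,
        "aggregate_all": agg_all["all"],
        "aggregate_by_group": agg_by,
        "cohort_screw_contacts": cohort_contacts,
    }
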