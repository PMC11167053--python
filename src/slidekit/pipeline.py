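"""End-to-end pipeline orchestration.

Stages: patchify -> segment (per patch, resumable) -> resolve -> aggregate
-> annotate -> stats -> niches -> export -> report.  Each stage writes its
artifacts under the configured output directory and is skipped on re-run if
they already exist, so a failed run resumes where it stopped.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as skio
from .aggregation import average_channels, count_transcripts
from .annotation import annotate_by_markers, preprocess_intensities
from .conflicts import resolve_conflicts
from .core import RasterImage, TranscriptTable, ValidationError
from .explorer import write_bundle
from .graph import build_graph, hop_distance_matrix, build_network
from .niches import extract_niche_polygons, niche_stats
from .patching import PatchGrid, assign_transcripts, make_patches
from .segmentation import run_segmentation
from .synthetic import generate_tissue, _niche_label

log = logging.getLogger("slidekit")

STAGES = ("patchify", "segment", "resolve", "aggregate", "annotate", "stats",
          "niches", "export", "report")


def load_config(path: str | Path) -> dict:
    import yaml

    return yaml.safe_load(Path(path).read_text())


def _load_inputs(config: dict):
    if "generate" in config:
        params = dict(config["generate"])
        image, transcripts, truth = generate_tissue(**params)
        return image, transcripts, truth
    image, transcripts, _ = skio.load_dataset(config["dataset"])
    return image, transcripts, None


def run_pipeline(config: dict, stages: list[str] | None = None,
                 patch_index: int | None = None) -> dict:
    """Execute the requested pipeline stages; returns artifact paths.

    ``config`` keys: ``outdir``; either ``generate`` (synthetic parameters)
    or ``dataset`` (paths); optional ``patch`` (width/overlap µm),
    ``segmentation`` (built-in segmenter params), ``merge_threshold``,
    ``markers`` (channel -> population), ``max_edge_length``,
    ``partition_size``, ``niche_mode``.
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    selected = list(STAGES) if stages is None else list(stages)
    unknown = set(selected) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stages: {sorted(unknown)}")

    image, transcripts, truth = _load_inputs(config)
    art = {name: outdir / name for name in ()}
    paths = {
        "grid": outdir / "grid.geojson",
        "patch_dir": outdir / "patches",
        "cells": outdir / "cells.geojson",
        "conflicts": outdir / "conflicts.csv",
        "channel_means": outdir / "channel_means.csv",
        "counts": outdir / "counts.mtx",
        "labels": outdir / "labels.csv",
        "stats_dir": outdir / "stats",
        "niches": outdir / "niche_components.geojson",
        "niche_stats": outdir / "niche_stats.csv",
        "bundle": outdir / "bundle",
        "report": outdir / "report.html",
    }

    def stage(name: str, done) -> bool:
        if name not in selected:
            return False
        if done():
            log.info("stage %s: outputs exist, skipped", name)
            return False
        return True

    t0 = time.monotonic()
    if stage("patchify", paths["grid"].exists):
        grid = make_patches(image.extent,
                            float(config.get("patch", {}).get("width", 200.0)),
                            float(config.get("patch", {}).get("overlap", 40.0)))
        grid.to_geojson(paths["grid"])
        log.info("patchify: %d patches (%.2fs)", len(grid), time.monotonic() - t0)

    if "segment" in selected or "resolve" in selected:
        grid = PatchGrid.from_geojson(paths["grid"])

    if "segment" in selected:
        paths["patch_dir"].mkdir(exist_ok=True)
        indices = range(len(grid)) if patch_index is None else [patch_index]
        seg_params = dict(config.get("segmentation", {}))
        for idx in indices:
            out = paths["patch_dir"] / f"patch_{idx}.geojson"
            if out.exists():
                log.info("segment: patch %d exists, skipped", idx)
                continue
            t = time.monotonic()
            (coll,) = run_segmentation(image, grid, params=seg_params,
                                       transcripts=transcripts, patch_indices=[idx])
            skio.write_cells(coll, out)
            log.info("segment: patch %d -> %d cells (%.2fs)", idx, len(coll),
                     time.monotonic() - t)

    if stage("resolve", paths["cells"].exists):
        per_patch = [skio.read_cells(paths["patch_dir"] / f"patch_{i}.geojson")
                     for i in range(len(grid))]
        result = resolve_conflicts(per_patch, float(config.get("merge_threshold", 0.5)))
        skio.write_cells(result.cells, paths["cells"])
        result.conflicts.to_csv(paths["conflicts"], index=False)
        log.info("resolve: %d cells, %d conflicts", len(result.cells),
                 len(result.conflicts))

    cells = skio.read_cells(paths["cells"]) if paths["cells"].exists() else None

    if stage("aggregate", lambda: paths["channel_means"].exists()):
        X = average_channels(image, cells)
        pd.DataFrame(X.X, index=X.cell_ids, columns=X.channels).to_csv(
            paths["channel_means"], index_label="cell_id")
        if transcripts is not None:
            counts, unassigned = count_transcripts(
                transcripts, cells, float(config.get("partition_size", 100.0)))
            skio.write_counts(counts, paths["counts"])
            (outdir / "unassigned.json").write_text(json.dumps(
                {"unassigned": unassigned, "total": len(transcripts)}))
        log.info("aggregate: done")

    if stage("annotate", paths["labels"].exists):
        means = pd.read_csv(paths["channel_means"], index_col="cell_id")
        from .core import ChannelMatrix

        X = ChannelMatrix(means.to_numpy(), list(means.columns),
                          means.index.to_numpy())
        markers = config.get("markers") or {}
        labels = (annotate_by_markers(preprocess_intensities(X), markers)
                  if markers else ["unassigned"] * len(cells))
        size = float(config.get("generate", {}).get("image_size_um", 0)) or None
        mode = config.get("niche_mode",
                          config.get("generate", {}).get("niche_mode", "halves"))
        niche = [(_niche_label(c, size, mode) if size else "niche_0")
                 for c in cells.centroids]
        pd.DataFrame({"cell_id": cells.cell_ids, "cell_type": labels,
                      "niche": niche}).to_csv(paths["labels"], index=False)
        log.info("annotate: %d cells labeled", len(labels))

    if stage("stats", paths["stats_dir"].exists):
        labels_df = pd.read_csv(paths["labels"]).set_index("cell_id")
        sg = build_graph(cells, float(config.get("max_edge_length", 40.0)))
        ctype = labels_df.loc[cells.cell_ids, "cell_type"].tolist()
        cniche = labels_df.loc[cells.cell_ids, "niche"].tolist()
        paths["stats_dir"].mkdir(exist_ok=True)
        mats = {}
        for (rname, row), (cname, col) in [(("type", ctype), ("type", ctype)),
                                           (("type", ctype), ("niche", cniche)),
                                           (("niche", cniche), ("type", ctype)),
                                           (("niche", cniche), ("niche", cniche))]:
            res = hop_distance_matrix(sg, row, col)
            res.D.to_csv(paths["stats_dir"] / f"D_{rname}_{cname}.csv")
            mats[(rname, cname)] = res.D
        net = build_network(mats)
        pd.DataFrame([(u, v, d["distance"], d["weight"])
                      for u, v, d in net.edges(data=True)],
                     columns=["u", "v", "distance", "weight"]).to_csv(
            paths["stats_dir"] / "network_edges.csv", index=False)
        log.info("stats: distance matrices + network written")

    if stage("niches", paths["niche_stats"].exists):
        labels_df = pd.read_csv(paths["labels"]).set_index("cell_id")
        sg = build_graph(cells, float(config.get("max_edge_length", 40.0)))
        cniche = labels_df.loc[cells.cell_ids, "niche"].tolist()
        comps = extract_niche_polygons(sg, cniche)
        table = niche_stats(comps)
        table.to_csv(paths["niche_stats"])
        features = [{"type": "Feature",
                     "geometry": comp.polygon.__geo_interface__,
                     "properties": {"niche": comp.niche, "area": comp.area,
                                    "perimeter": comp.perimeter,
                                    "roundness": comp.roundness,
                                    "n_cells": comp.n_cells}}
                    for comp in comps]
        paths["niches"].write_text(json.dumps(
            {"type": "FeatureCollection", "features": features}))
        log.info("niches: %d components", len(comps))

    if stage("export", (paths["bundle"] / "experiment.json").exists):
        counts = skio.read_counts(paths["counts"]) if paths["counts"].exists() else None
        categories = None
        if paths["labels"].exists():
            labels_df = pd.read_csv(paths["labels"])
            categories = {"cell_type": labels_df["cell_type"].tolist(),
                          "niche": labels_df["niche"].tolist()}
        write_bundle(paths["bundle"], image=image, transcripts=transcripts,
                     cells=cells, counts=counts, categories=categories,
                     name=config.get("name", "slidekit-run"))
        log.info("export: bundle written")

    if stage("report", paths["report"].exists):
        from .report import make_report

        make_report(outdir, paths["report"])
        log.info("report: written")

    return {k: str(v) for k, v in paths.items()}
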