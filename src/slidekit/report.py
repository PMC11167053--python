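"""Single-file HTML quality-control report for a pipeline run."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .conflicts import classify_conflict


def _section(title: str, body: str) -> str:
    return f"<section><h2>{title}</h2>{body}</section>\n"


def _table(df: pd.DataFrame) -> str:
    return df.to_html(border=0, float_format=lambda v: f"{v:.4g}")


def make_report(outdir: str | Path, target: str | Path | None = None) -> str:
    """Build the QC report from the artifacts in ``outdir``.

    Sections with missing artifacts are replaced by a notice rather than
    failing.  Returns the HTML; writes it to ``target`` when given.
    """
    outdir = Path(outdir)
    parts = ["<html><head><meta charset='utf-8'><title>slidekit QC report</title>",
             "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:"
             "collapse}td,th{padding:2px 8px;border-bottom:1px solid #ddd}</style>",
             "</head><body><h1>Pipeline QC report</h1>"]

    cells_path = outdir / "cells.geojson"
    if cells_path.exists():
        doc = json.loads(cells_path.read_text())
        n = len(doc["features"])
        from shapely.geometry import shape

        areas = pd.Series([shape(f["geometry"]).area for f in doc["features"]])
        body = (f"<p>Resolved cells: <b>{n}</b></p>"
                + _table(areas.describe().to_frame("cell area (µm²)")))
        parts.append(_section("Cells", body))
    else:
        parts.append(_section("Cells", "<p>No resolved cell set found.</p>"))

    conflicts_path = outdir / "conflicts.csv"
    if conflicts_path.exists():
        table = pd.read_csv(conflicts_path)
        if len(table):
            bins = (table["ioma"].map(classify_conflict)
                    .value_counts()
                    .reindex(["good_distinct", "ambiguous", "good_duplicate"],
                             fill_value=0))
        else:
            bins = pd.Series(0, index=["good_distinct", "ambiguous", "good_duplicate"])
        body = (f"<p>Cross-patch conflicts: <b>{len(table)}</b></p>"
                + _table(bins.to_frame("conflicts")))
        parts.append(_section("Conflict quality", body))
    else:
        parts.append(_section("Conflict quality", "<p>No conflict table found.</p>"))

    unassigned_path = outdir / "unassigned.json"
    if unassigned_path.exists():
        info = json.loads(unassigned_path.read_text())
        total = max(info["total"], 1)
        frac = 1 - info["unassigned"] / total
        parts.append(_section(
            "Transcripts",
            f"<p>Assigned to cells: <b>{frac:.1%}</b> of {info['total']}</p>"))

    means_path = outdir / "channel_means.csv"
    if means_path.exists():
        means = pd.read_csv(means_path, index_col="cell_id")
        parts.append(_section("Channel intensities", _table(means.describe().T)))

    labels_path = outdir / "labels.csv"
    if labels_path.exists():
        labels = pd.read_csv(labels_path)
        body = (_table(labels["cell_type"].value_counts().to_frame("cells"))
                + _table(labels["niche"].value_counts().to_frame("cells")))
        parts.append(_section("Annotation", body))

    parts.append("</body></html>")
    html = "\n".join(parts)
    if target is not None:
        Path(target).write_text(html)
    return html
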