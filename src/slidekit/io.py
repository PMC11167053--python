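"""Readers and writers for the standard on-disk formats.

Images are read from OME-TIFF (via tifffile) or Zarr; transcripts from
CSV/parquet; cell boundaries from/to GeoJSON FeatureCollections; count
matrices from/to MatrixMarket triplets with sidecar gene/cell lists.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from shapely.geometry import shape as geojson_shape, mapping as geojson_mapping

from .core import (CellCollection, CountsMatrix, RasterImage, TranscriptTable,
                   ValidationError)


class LoadError(IOError):
    """Raised when a referenced input file is missing or unreadable."""


def read_image(path: str | Path, pixel_size: float,
               channel_names: list[str] | None = None,
               chunk_shape: tuple[int, int] = (1024, 1024)) -> RasterImage:
    """Read a (C, H, W) image from OME-TIFF or a Zarr array directory."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"image file not found: {path}")
    if path.suffix in {".zarr"} or path.is_dir():
        import zarr

        data = zarr.open_array(str(path), mode="r")
    else:
        import tifffile

        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    if channel_names is None:
        channel_names = [f"channel_{i}" for i in range(data.shape[0])]
    return RasterImage(data, channel_names, pixel_size, chunk_shape)


def write_image(image: RasterImage, path: str | Path) -> None:
    """Write the image as OME-TIFF (suffix .tif/.tiff) or a Zarr array."""
    path = Path(path)
    if path.suffix in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, np.asarray(image.data),
                         metadata={"axes": "CYX",
                                   "Channel": {"Name": image.channel_names}})
    else:
        import zarr

        arr = zarr.create_array(str(path), shape=image.shape,
                                dtype=np.asarray(image.data[:, :1, :1]).dtype,
                                chunks=(1, *image.chunk_shape), overwrite=True)
        arr[:] = np.asarray(image.data)


def read_transcripts(path: str | Path, vocabulary: list[str] | None = None,
                     ) -> TranscriptTable:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"transcript file not found: {path}")
    if path.suffix in {".parquet", ".pq"}:
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    return TranscriptTable.from_arrays(df["x"], df["y"], df["gene"], vocabulary)


def write_transcripts(t: TranscriptTable, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in {".parquet", ".pq"}:
        t.df.to_parquet(path, index=False)
    else:
        t.df.to_csv(path, index=False)


def write_cells(cells: CellCollection, path: str | Path) -> None:
    """Write cell boundaries as a GeoJSON FeatureCollection (world µm)."""
    features = []
    for cid, poly, prov in zip(cells.cell_ids, cells.polygons, cells.provenance):
        features.append({
            "type": "Feature",
            "geometry": geojson_mapping(poly),
            "properties": {"cell_id": int(cid), "patches": sorted(int(p) for p in prov)},
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))


def read_cells(path: str | Path) -> CellCollection:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"cell boundary file not found: {path}")
    doc = json.loads(path.read_text())
    ids, polys, prov = [], [], []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        ids.append(int(props.get("cell_id", i)))
        polys.append(geojson_shape(feat["geometry"]))
        prov.append(frozenset(props.get("patches", ())))
    return CellCollection(np.array(ids, dtype=np.int64), polys, prov)


def write_counts(counts: CountsMatrix, path: str | Path) -> None:
    """Write an MTX triplet plus `<stem>_genes.txt` and `<stem>_cells.txt` sidecars."""
    path = Path(path)
    spio.mmwrite(str(path), counts.matrix.tocoo(), field="integer")
    path.with_name(path.stem + "_genes.txt").write_text("\n".join(counts.genes) + "\n")
    path.with_name(path.stem + "_cells.txt").write_text(
        "\n".join(str(int(c)) for c in counts.cell_ids) + "\n")


def read_counts(path: str | Path) -> CountsMatrix:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"counts file not found: {path}")
    mat = sparse.csr_matrix(spio.mmread(str(path)))
    genes = path.with_name(path.stem + "_genes.txt").read_text().splitlines()
    cell_ids = np.array(path.with_name(path.stem + "_cells.txt").read_text().split(),
                        dtype=np.int64)
    return CountsMatrix(mat, genes, cell_ids)


def load_dataset(config: dict | str | Path,
                 ) -> tuple[RasterImage, TranscriptTable | None, CellCollection | None]:
    """Load a dataset described by a config record (or YAML/JSON file path).

    Recognised keys: ``image`` (path), ``pixel_size`` (µm/px, required with
    image), ``channel_names``, ``chunk_shape``, ``transcripts`` (path),
    ``cells`` (path).
    """
    if not isinstance(config, dict):
        cfg_path = Path(config)
        if not cfg_path.exists():
            raise LoadError(f"config file not found: {cfg_path}")
        text = cfg_path.read_text()
        if cfg_path.suffix in {".yaml", ".yml"}:
            import yaml

            config = yaml.safe_load(text)
        else:
            config = json.loads(text)
        base = cfg_path.parent
        for key in ("image", "transcripts", "cells"):
            if config.get(key) and not Path(config[key]).is_absolute():
                config[key] = str(base / config[key])
    if "image" not in config:
        raise ValidationError("dataset config must name an image")
    pixel_size = float(config.get("pixel_size", 0))
    if pixel_size <= 0:
        raise ValidationError(f"pixel_size must be > 0, got {pixel_size}")
    image = read_image(config["image"], pixel_size,
                       config.get("channel_names"),
                       tuple(config.get("chunk_shape", (1024, 1024))))
    transcripts = (read_transcripts(config["transcripts"])
                   if config.get("transcripts") else None)
    cells = read_cells(config["cells"]) if config.get("cells") else None
    return image, transcripts, cells
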