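"""File formats: TIFF scans with JSON sidecars, CSV/JSON result tables.

Raster counts are stored as unsigned 16-bit multi-frame TIFF (one file per
channel); line scans as a single 2-D TIFF.  A JSON sidecar with the same
basename carries the acquisition settings, seed and (for synthetic data)
the ground truth.  Result tables are CSV stamped with a config hash and
seed; float maps (brightness etc.) go to 32-bit float TIFF.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import (LineScanSeries, RasterSeries, ReferenceImage,
                        ScanConfig)

__all__ = [
    "save_scan",
    "load_scan",
    "save_results",
    "config_hash",
]


def config_hash(config: ScanConfig, seed=None) -> str:
    payload = json.dumps({**config.to_dict(), "seed": seed}, sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_scan(series, path) -> Path:
    """Write a raster or line-scan series as TIFF + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": series.config.to_dict(),
        "seed": series.seed,
        "ground_truth": series.ground_truth,
    }
    if isinstance(series, RasterSeries):
        meta["mode"] = "raster"
        tifffile.imwrite(path, np.asarray(series.counts).astype(np.uint16),
                         photometric="minisblack")
        if series.counts2 is not None:
            red = path.with_name(path.stem + "_ch2" + path.suffix)
            tifffile.imwrite(red, np.asarray(series.counts2).astype(np.uint16),
                             photometric="minisblack")
            meta["channel2"] = red.name
    elif isinstance(series, LineScanSeries):
        meta["mode"] = "line"
        tifffile.imwrite(path, np.asarray(series.counts).astype(np.uint16),
                         photometric="minisblack")
        for tag in ("reference_before", "reference_after"):
            ref = getattr(series, tag)
            if ref is not None:
                meta[tag] = {"fluor": ref.fluor.tolist(),
                             "marker": ref.marker.tolist()}
    else:
        raise TypeError(f"cannot save {type(series).__name__}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_scan(path, config_overrides: dict | None = None):
    """Load a TIFF scan, merging sidecar metadata with overrides.

    Overrides win over the sidecar; a scan without a sidecar needs the
    acquisition timing supplied via overrides.
    """
    path = Path(path)
    counts = tifffile.imread(path)
    if np.issubdtype(counts.dtype, np.floating):
        counts = counts.astype(np.float64)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    cfg_dict = dict(meta.get("config", {}))
    if config_overrides:
        cfg_dict.update(config_overrides)
    missing = [k for k in ("pixel_size", "pixel_dwell", "line_time")
               if k not in cfg_dict]
    if missing:
        raise ValueError("missing acquisition metadata and no override for: "
                         + ", ".join(missing))
    mode = meta.get("mode", "raster" if counts.ndim == 3 else "line")
    if mode == "raster":
        cfg_dict.setdefault("frame_count", counts.shape[0])
        cfg_dict.setdefault("image_size", counts.shape[-1])
        config = ScanConfig.from_dict(cfg_dict)
        if counts.shape[0] != config.frame_count:
            raise ValueError("file truncated: frame count does not match "
                             "metadata")
        counts2 = None
        if meta.get("channel2"):
            counts2 = tifffile.imread(path.with_name(meta["channel2"]))
        return RasterSeries(counts=counts, config=config, counts2=counts2,
                            ground_truth=meta.get("ground_truth"),
                            seed=meta.get("seed"))
    cfg_dict.setdefault("n_lines", counts.shape[0])
    cfg_dict.setdefault("line_length", counts.shape[1])
    config = ScanConfig.from_dict(cfg_dict)
    refs = {}
    for tag in ("reference_before", "reference_after"):
        if tag in meta:
            refs[tag] = ReferenceImage(
                fluor=np.asarray(meta[tag]["fluor"]),
                marker=np.asarray(meta[tag]["marker"]))
    return LineScanSeries(counts=counts, config=config,
                          ground_truth=meta.get("ground_truth"),
                          seed=meta.get("seed"), **refs)


def save_results(results: dict, out_dir, stage: str = "results",
                 config: ScanConfig | None = None, seed=None) -> list:
    """Write a stage's outputs: DataFrames to CSV, dicts to JSON, arrays to
    float TIFF.  Every file is stamped (in name) with the config hash/seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = config_hash(config, seed) if config is not None else "nohash"
    written = []
    for name, obj in results.items():
        base = f"{stage}_{name}_{stamp}"
        if isinstance(obj, pd.DataFrame):
            p = out / f"{base}.csv"
            obj.to_csv(p, index=False)
        elif isinstance(obj, np.ndarray):
            p = out / f"{base}.tif"
            tifffile.imwrite(p, obj.astype(np.float32),
                             photometric="minisblack")
        elif isinstance(obj, dict):
            p = out / f"{base}.json"
            p.write_text(json.dumps(obj, indent=1, default=_jsonable))
        else:
            raise TypeError(f"cannot save result '{name}' of type "
                            f"{type(obj).__name__}")
        written.append(p)
    return written


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o).__name__}")
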