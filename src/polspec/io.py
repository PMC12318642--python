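"""File-format plumbing: TIFF rasters with JSON sidecars, CSV curves.

TIFF is the raster interchange format throughout (multi-page for cubes and
channel stacks); every raster gets a JSON sidecar carrying grid, seed, layout
and other metadata, since TIFF tags are dialect-prone. Curves travel as CSV.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .optics import (
    FOUR_DETECTOR_CHANNELS,
    POLARSENS_CHANNELS,
    ChannelImages,
    InstrumentConfig,
    RawMosaicFrame,
)
from .smv import ResponseCurve, SMVImage
from .spectra import HyperspectralScene, SpectralGrid
from .analysis import Gate, ReferenceSet

__all__ = [
    "write_scene",
    "read_scene",
    "write_channels",
    "read_channels",
    "write_mosaic",
    "read_mosaic",
    "write_smv_image",
    "read_smv_image",
    "write_response_curve",
    "read_response_curve",
    "write_label_map",
    "read_label_map",
    "write_abundances",
    "write_rgb",
    "load_gates",
    "dump_gates",
    "load_references",
    "dump_references",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def _grid_meta(grid: SpectralGrid) -> dict:
    lam = grid.wavelengths_nm
    step = np.diff(lam)
    if np.allclose(step, step[0]):
        return {"start_nm": lam[0], "stop_nm": lam[-1], "n": int(lam.size)}
    return {"wavelengths_nm": lam.tolist()}


def _grid_from_meta(meta: dict) -> SpectralGrid:
    if "wavelengths_nm" in meta:
        return SpectralGrid(np.asarray(meta["wavelengths_nm"]))
    return SpectralGrid(np.linspace(meta["start_nm"], meta["stop_nm"], meta["n"]))


def _config_meta(config: InstrumentConfig) -> dict:
    er = config.extinction_ratio
    return {
        "config_kind": config.config_kind,
        "retardance_nm": config.retardance_nm,
        "extinction_ratio": None if math.isinf(er) else er,
        "mosaic_layout": [list(r) for r in config.mosaic_layout],
    }


def _config_from_meta(meta: dict) -> InstrumentConfig:
    er = meta.get("extinction_ratio")
    return InstrumentConfig(
        config_kind=meta["config_kind"],
        retardance_nm=meta["retardance_nm"],
        extinction_ratio=math.inf if er is None else er,
        mosaic_layout=tuple(tuple(r) for r in meta["mosaic_layout"]),
    )


# ---------------------------------------------------------------------------
# Scenes


def write_scene(path: str | Path, scene: HyperspectralScene) -> None:
    """Scene cube as multi-page grayscale TIFF (one page per wavelength)."""
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(scene.cube, 2, 0).astype(np.float32), photometric="minisblack")
    meta = {"grid": _grid_meta(scene.grid), "kind": "scene"}
    if scene.meta.get("seed") is not None:
        meta["seed"] = scene.meta["seed"]
    if scene.component_names:
        meta["component_names"] = scene.component_names
    if scene.labels is not None:
        label_path = path.with_name(path.stem + "_labels.tif")
        write_label_map(label_path, scene.labels)
        meta["labels_file"] = label_path.name
    if scene.abundances is not None:
        ab_path = path.with_name(path.stem + "_abundances.tif")
        write_abundances(ab_path, scene.abundances)
        meta["abundances_file"] = ab_path.name
    _write_json(_sidecar(path), meta)


def read_scene(path: str | Path) -> HyperspectralScene:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    cube = np.moveaxis(tifffile.imread(path).astype(float), 0, 2)
    labels = abundances = None
    if "labels_file" in meta:
        labels = read_label_map(path.with_name(meta["labels_file"]))
    if "abundances_file" in meta:
        abundances = np.moveaxis(
            tifffile.imread(path.with_name(meta["abundances_file"])).astype(float), 0, 2
        )
    return HyperspectralScene(
        grid=_grid_from_meta(meta["grid"]),
        cube=cube,
        labels=labels,
        abundances=abundances,
        component_names=meta.get("component_names"),
        meta={"seed": meta.get("seed")},
    )


# ---------------------------------------------------------------------------
# Channels and mosaic frames


def write_channels(path: str | Path, channels: ChannelImages) -> None:
    """Channel quartet as 4-page TIFF, page order I0, I45, I90, I135."""
    path = Path(path)
    order = (
        POLARSENS_CHANNELS
        if channels.config.config_kind == "polarsens_single_shot"
        else FOUR_DETECTOR_CHANNELS
    )
    pages = np.stack([np.atleast_2d(channels[k]) for k in order]).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    _write_json(
        _sidecar(path),
        {"kind": "channels", "page_order": list(order), "config": _config_meta(channels.config)},
    )


def read_channels(path: str | Path) -> ChannelImages:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    pages = tifffile.imread(path).astype(float)
    channels = {k: pages[i] for i, k in enumerate(meta["page_order"])}
    return ChannelImages(channels=channels, config=_config_from_meta(meta["config"]))


def write_mosaic(path: str | Path, raw: RawMosaicFrame) -> None:
    path = Path(path)
    tifffile.imwrite(path, raw.frame.astype(np.float32))
    _write_json(
        _sidecar(path),
        {
            "kind": "mosaic",
            "layout": [list(r) for r in raw.layout],
            "seed": raw.seed,
            "noise": raw.noise,
            "config": _config_meta(raw.config),
        },
    )


def read_mosaic(path: str | Path) -> RawMosaicFrame:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return RawMosaicFrame(
        frame=tifffile.imread(path).astype(float),
        layout=tuple(tuple(r) for r in meta["layout"]),
        config=_config_from_meta(meta["config"]),
        seed=meta.get("seed"),
        noise=meta.get("noise", {}),
    )


# ---------------------------------------------------------------------------
# SMV images, curves, maps


def write_smv_image(path: str | Path, smv: SMVImage) -> None:
    """SMV image as float TIFF pages (V1..VN, total) plus mask TIFF."""
    path = Path(path)
    pages = np.concatenate(
        [np.moveaxis(smv.v, 2, 0), smv.total_intensity[None]], axis=0
    ).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    mask_path = path.with_name(path.stem + "_mask.tif")
    tifffile.imwrite(mask_path, smv.valid.astype(np.uint8))
    _write_json(
        _sidecar(path),
        {"kind": "smv", "n_components": smv.n_components, "mask_file": mask_path.name},
    )


def read_smv_image(path: str | Path) -> SMVImage:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    pages = tifffile.imread(path).astype(float)
    n = meta["n_components"]
    mask = tifffile.imread(path.with_name(meta["mask_file"])).astype(bool)
    return SMVImage(v=np.moveaxis(pages[:n], 0, 2), total_intensity=pages[n], valid=mask)


def write_response_curve(path: str | Path, curve: ResponseCurve) -> None:
    curve.to_frame().to_csv(path, index=False)


def read_response_curve(path: str | Path, retardance_nm: float | None = None) -> ResponseCurve:
    return ResponseCurve.from_frame(pd.read_csv(path), retardance_nm)


def write_label_map(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(Path(path), labels.astype(np.int32))


def read_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_abundances(path: str | Path, abundances: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.moveaxis(abundances, 2, 0).astype(np.float32), photometric="minisblack")


def write_rgb(path: str | Path, rgb: np.ndarray) -> None:
    """8-bit PNG/TIFF export of a [0, 1] float RGB image."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.clip(rgb, 0, 1) * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# Gates and references (JSON)


def dump_gates(path: str | Path, gates: list[Gate]) -> None:
    _write_json(
        Path(path),
        {
            "gates": [
                {"label": g.label, "polygon": [list(v) for v in g.polygon], "priority": g.priority}
                for g in gates
            ]
        },
    )


def load_gates(path: str | Path) -> list[Gate]:
    payload = json.loads(Path(path).read_text())
    return [
        Gate(label=g["label"], polygon=tuple(tuple(v) for v in g["polygon"]),
             priority=g.get("priority", 0))
        for g in payload["gates"]
    ]


def dump_references(path: str | Path, refs: ReferenceSet) -> None:
    _write_json(
        Path(path),
        {"labels": refs.labels, "vectors": refs.vectors.tolist()},
    )


def load_references(path: str | Path) -> ReferenceSet:
    payload = json.loads(Path(path).read_text())
    return ReferenceSet(vectors=np.asarray(payload["vectors"]), labels=list(payload["labels"]))
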