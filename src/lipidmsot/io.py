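"""Round-trip I/O: HDF5 study containers, PNG masks, CSV tables, provenance.

Study container layout:
    /frames        (T, L, H, W) float32
    /labels        (H, W) uint8 compartment label map
    /time_points   (T,) minutes
    /wavelengths   (L,) nm
    /ground_truth/masks/<compartment>   (H, W) uint8 {0, 1}
    attrs: pixel_pitch_mm, skin_row, seed, kinetics (JSON), mixtures (JSON)

Masks are additionally exchanged as single-channel PNGs (0 = out, 255 = in)
with a JSON sidecar recording compartment, rater and pixel pitch.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import h5py
import imageio.v3 as iio
import numpy as np

from .kinetics import KineticParams
from .phantom import TissueGeometry
from .roi import ROIMask, TimeCourse
from .simulate import AcquisitionSchedule, MultispectralStudy
from .spectra import ChromophoreMixture

__all__ = [
    "save_study",
    "load_study",
    "save_mask_png",
    "load_mask_png",
    "timecourse_to_csv",
    "write_provenance",
]


def save_study(study: MultispectralStudy, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=study.frames, dtype="float32")
        f.create_dataset("labels", data=study.geometry.label_map, dtype="uint8")
        f.create_dataset("time_points", data=study.schedule.time_points)
        f.create_dataset("wavelengths", data=study.schedule.wavelengths)
        gt = f.create_group("ground_truth/masks")
        for name, mask in study.ground_truth_masks.items():
            gt.create_dataset(name, data=mask.astype(np.uint8))
        f.attrs["pixel_pitch_mm"] = study.geometry.pixel_pitch
        f.attrs["skin_row"] = study.geometry.skin_row
        f.attrs["seed"] = study.seed
        f.attrs["kinetics"] = study.kinetics_json()
        f.attrs["mixtures"] = json.dumps(
            {k: dict(v.concentrations) for k, v in study.mixtures.items()}
        )
    return path


def load_study(path: str | Path) -> MultispectralStudy:
    with h5py.File(path, "r") as f:
        frames = f["frames"][()]
        geometry = TissueGeometry(
            label_map=f["labels"][()],
            pixel_pitch=float(f.attrs["pixel_pitch_mm"]),
            skin_row=int(f.attrs["skin_row"]),
        )
        schedule = AcquisitionSchedule(
            time_points=f["time_points"][()], wavelengths=f["wavelengths"][()]
        )
        kinetics = {
            name: KineticParams(**params)
            for name, params in json.loads(f.attrs["kinetics"]).items()
        }
        mixtures = {
            name: ChromophoreMixture(conc)
            for name, conc in json.loads(f.attrs["mixtures"]).items()
        }
        seed = int(f.attrs["seed"])
    return MultispectralStudy(
        frames=frames, schedule=schedule, geometry=geometry,
        kinetics=kinetics, mixtures=mixtures, seed=seed,
    )


def save_mask_png(
    roi: ROIMask, path: str | Path, pixel_pitch: float | None = None
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (roi.mask.astype(np.uint8)) * 255)
    sidecar = {
        "compartment": roi.compartment,
        "rater": roi.rater,
        "pixel_pitch_mm": pixel_pitch,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_mask_png(path: str | Path) -> ROIMask:
    path = Path(path)
    img = np.asarray(iio.imread(path))
    if img.ndim != 2:
        raise ValueError(f"{path}: mask PNG must be single-channel")
    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ROIMask(
        mask=img > 127,
        compartment=meta.get("compartment", "unknown"),
        rater=meta.get("rater", "unknown"),
    )


def timecourse_to_csv(tc: TimeCourse, path: str | Path) -> Path:
    """CSV columns: time_min,value,normalized_value (empty if not normalized)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    norm = tc.normalized_values
    with open(path, "w") as f:
        f.write("time_min,value,normalized_value\n")
        for i, (t, v) in enumerate(zip(tc.times, tc.values)):
            n = "" if norm is None else f"{norm[i]:.10g}"
            f.write(f"{t:g},{v:.10g},{n}\n")
    return path


def write_provenance(
    out_path: str | Path, stage: str, seed: int | None, config: Mapping | None
) -> Path:
    """JSON sidecar tying an output to its seed and config hash."""
    from . import __version__

    cfg_json = json.dumps(config, sort_keys=True, default=str) if config else ""
    record = {
        "stage": stage,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest() if cfg_json else None,
        "tool": "lipidmsot",
        "version": __version__,
    }
    out_path = Path(out_path)
    prov = out_path.with_name(out_path.name + ".provenance.json")
    prov.write_text(json.dumps(record, indent=2))
    return prov
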