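"""File I/O: HDF5 M-scan cubes, TIFF amplitude images, JSON models/configs.

Conventions
-----------
* M-scan cubes live in HDF5: datasets ``/phase`` (float32, depth x lateral x
  time) and ``/intensity_db`` (float32), one attribute per simulation-config
  field, optional group ``/latent`` with the simulator's hidden parameters
  and group ``/layout`` with the phantom geometry.
* Amplitude images are float32 TIFFs (NaN on masked-out pixels) with a JSON
  sidecar recording kind, samples used and mask statistics.
* Network weights are plain JSON: layer sizes, per-layer weight/bias arrays,
  a config echo and the training seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .lockin import PTImage
from .ptnet import NetworkConfig, NetworkParams
from .synth import LatentTruth, MScanCube, PhantomLayout, SimulationConfig

__all__ = [
    "save_mscan",
    "load_mscan",
    "save_image",
    "load_image",
    "save_model",
    "load_model",
    "layout_to_dict",
    "layout_from_dict",
    "config_hash",
]


def _asdict_plain(obj) -> dict:
    """Dataclass -> dict with numpy values converted to plain Python."""
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, (np.integer, np.floating)):
            v = v.item()
        elif isinstance(v, dict):
            v = {str(k): float(x) for k, x in v.items()}
        out[f.name] = v
    return out


def config_hash(*objs) -> str:
    """Short deterministic hash of one or more dataclass configs."""
    payload = json.dumps([_asdict_plain(o) for o in objs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def layout_to_dict(layout: PhantomLayout) -> dict:
    return {
        "n_lateral": layout.n_lateral,
        "n_depth": layout.n_depth,
        "region_labels": layout.region_labels.tolist(),
        "region_powers_mw": {str(k): float(v) for k, v in layout.region_powers_mw.items()},
        "absorber_mask": layout.absorber_mask.astype(int).tolist(),
        "surface_row": layout.surface_row,
    }


def layout_from_dict(d: dict) -> PhantomLayout:
    return PhantomLayout(
        n_lateral=int(d["n_lateral"]),
        n_depth=int(d["n_depth"]),
        region_labels=np.asarray(d["region_labels"], dtype=int),
        region_powers_mw={int(k): float(v) for k, v in d["region_powers_mw"].items()},
        absorber_mask=np.asarray(d["absorber_mask"], dtype=bool),
        surface_row=int(d["surface_row"]),
    )


def save_mscan(
    path: str | Path, cube: MScanCube, latent: LatentTruth | None = None
) -> None:
    """Write an M-scan cube (and optionally its latent truth) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("phase", data=cube.phase_rad.astype(np.float32))
        f.create_dataset("intensity_db", data=cube.oct_intensity_db.astype(np.float32))
        for k, v in _asdict_plain(cube.config).items():
            f.attrs[k] = v
        if cube.layout is not None:
            g = f.create_group("layout")
            g.create_dataset("region_labels", data=cube.layout.region_labels)
            g.create_dataset(
                "absorber_mask", data=cube.layout.absorber_mask.astype(np.uint8)
            )
            g.attrs["surface_row"] = cube.layout.surface_row
            g.attrs["region_powers_mw"] = json.dumps(
                {str(k): float(v) for k, v in cube.layout.region_powers_mw.items()}
            )
        if latent is not None:
            g = f.create_group("latent")
            g.create_dataset("amplitude_rad", data=latent.amplitude_rad)
            g.create_dataset("transient_plateau_rad", data=latent.transient_plateau_rad)
            g.create_dataset("transient_tau_s", data=latent.transient_tau_s)


def load_mscan(path: str | Path) -> tuple[MScanCube, LatentTruth | None]:
    with h5py.File(path, "r") as f:
        cfg_fields = {f_.name for f_ in dataclasses.fields(SimulationConfig)}
        attrs = {k: v for k, v in f.attrs.items() if k in cfg_fields}
        if "snr_dependent_noise" in attrs:
            attrs["snr_dependent_noise"] = bool(attrs["snr_dependent_noise"])
        for int_key in ("n_samples", "focal_depth_px", "seed"):
            if int_key in attrs:
                attrs[int_key] = int(attrs[int_key])
        config = SimulationConfig(**attrs)
        layout = None
        if "layout" in f:
            g = f["layout"]
            labels = g["region_labels"][()]
            layout = PhantomLayout(
                n_lateral=labels.shape[1],
                n_depth=labels.shape[0],
                region_labels=labels,
                region_powers_mw={
                    int(k): float(v)
                    for k, v in json.loads(g.attrs["region_powers_mw"]).items()
                },
                absorber_mask=g["absorber_mask"][()].astype(bool),
                surface_row=int(g.attrs["surface_row"]),
            )
        cube = MScanCube(
            phase_rad=f["phase"][()].astype(float),
            oct_intensity_db=f["intensity_db"][()].astype(float),
            config=config,
            layout=layout,
        )
        latent = None
        if "latent" in f:
            g = f["latent"]
            latent = LatentTruth(
                amplitude_rad=g["amplitude_rad"][()],
                transient_plateau_rad=g["transient_plateau_rad"][()],
                transient_tau_s=g["transient_tau_s"][()],
            )
    return cube, latent


def save_image(path: str | Path, image: PTImage) -> None:
    """Float32 TIFF plus a JSON sidecar with kind and mask statistics."""
    path = Path(path)
    tifffile.imwrite(path, image.amplitude_rad.astype(np.float32))
    sidecar = {
        "kind": image.kind,
        "n_samples_used": image.n_samples_used,
        "n_masked_true": int(image.mask.sum()),
        "n_pixels": int(image.mask.size),
        "shape": list(image.shape),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def load_image(path: str | Path) -> PTImage:
    path = Path(path)
    amp = tifffile.imread(path).astype(float)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return PTImage(
        amplitude_rad=amp,
        mask=np.isfinite(amp),
        kind=sidecar["kind"],
        n_samples_used=sidecar["n_samples_used"],
    )


def save_model(
    path: str | Path,
    params: NetworkParams,
    net_config: NetworkConfig | None = None,
    seed: int | None = None,
) -> None:
    payload = {
        "layer_sizes": list(params.layer_sizes),
        "weights": [w.tolist() for w in params.weights],
        "biases": [b.tolist() for b in params.biases],
        "net_config": _asdict_plain(net_config) if net_config else None,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_model(path: str | Path) -> NetworkParams:
    d = json.loads(Path(path).read_text())
    return NetworkParams(
        weights=[np.asarray(w, dtype=float) for w in d["weights"]],
        biases=[np.asarray(b, dtype=float) for b in d["biases"]],
    )
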