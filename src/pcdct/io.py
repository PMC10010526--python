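"""File I/O helpers: HDF5 phantoms/sinograms, TIFF images, JSON models."""

from __future__ import annotations

import json

import h5py
import numpy as np
import tifffile

from .decomp import AtableModel, PolyModel
from .materials import BasisPair, get_material
from .phantoms import PhantomImage
from .projector import BinnedSinogram, FanBeamGeometry
from .recon import ReconImage

__all__ = [
    "save_phantom", "load_phantom",
    "save_sinogram", "load_sinogram",
    "save_image_tiff",
    "save_model_json", "load_model_json",
]


def save_phantom(phantom: PhantomImage, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("label_map", data=phantom.label_map,
                         compression="gzip")
        f.attrs["materials"] = list(phantom.materials)
        f.attrs["pixel_size_mm"] = phantom.pixel_size


def load_phantom(path) -> PhantomImage:
    with h5py.File(path, "r") as f:
        return PhantomImage(f["label_map"][()],
                            tuple(f.attrs["materials"]),
                            float(f.attrs["pixel_size_mm"]))


def _geom_attrs(g: FanBeamGeometry) -> dict:
    return {"sad": g.sad, "aid": g.aid, "n_views": g.n_views,
            "n_det": g.n_det, "det_pitch": g.det_pitch}


def save_sinogram(sino: BinnedSinogram, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=sino.counts, compression="gzip")
        f.create_dataset("blank", data=sino.blank)
        for k, v in _geom_attrs(sino.geometry).items():
            f.attrs[k] = v


def load_sinogram(path) -> BinnedSinogram:
    with h5py.File(path, "r") as f:
        geom = FanBeamGeometry(
            sad=float(f.attrs["sad"]), aid=float(f.attrs["aid"]),
            n_views=int(f.attrs["n_views"]), n_det=int(f.attrs["n_det"]),
            det_pitch=float(f.attrs["det_pitch"]))
        return BinnedSinogram(f["counts"][()], f["blank"][()], geom)


def save_image_tiff(image: ReconImage, path) -> None:
    """32-bit TIFF with pixel size recorded in the resolution tags."""
    res = 10.0 / image.pixel_size  # pixels per cm
    tifffile.imwrite(path, image.values.astype(np.float32),
                     resolution=(res, res), resolutionunit="CENTIMETER")


def save_model_json(model: PolyModel | AtableModel, path,
                    provenance: str = "") -> None:
    if isinstance(model, PolyModel):
        payload = {
            "kind": "poly",
            "d1": model.d1.tolist(),
            "d2": model.d2.tolist(),
            "fit_residual_cm": model.fit_residual,
        }
    else:
        payload = {
            "kind": "atable",
            "M": model.M.tolist(),
            "lut_nodes": model.lut_nodes.tolist(),
            "lut_values": model.lut_values.tolist(),
        }
    payload["basis"] = [model.basis.m1.name, model.basis.m2.name]
    payload["provenance"] = provenance
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model_json(path) -> PolyModel | AtableModel:
    with open(path) as fh:
        payload = json.load(fh)
    basis = BasisPair(get_material(payload["basis"][0]),
                      get_material(payload["basis"][1]))
    if payload["kind"] == "poly":
        return PolyModel(np.array(payload["d1"]), np.array(payload["d2"]),
                         basis, payload["fit_residual_cm"])
    return AtableModel(np.array(payload["M"]),
                       np.array(payload["lut_nodes"]),
                       np.array(payload["lut_values"]), basis)
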