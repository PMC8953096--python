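"""NIfTI / sidecar / provenance file I/O.

Multi-echo volumes travel as 4-D NIfTI (x, y, z, echo) with the echo
times in milliseconds in a JSON sidecar next to the image (NIfTI has no
standard per-volume TE field); an explicit echo-time argument always
overrides the sidecar.  Map stacks are written one 3-D NIfTI per map
plus the validity mask and a JSON provenance record (configuration,
seed, package version).  Writes go through a temporary file in the
destination directory and are renamed into place, so a failure leaves
no partial file behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .reconstruct import MapStack
from .signal import EchoTimes

__all__ = [
    "sidecar_path",
    "read_multiecho",
    "write_multiecho",
    "write_labels",
    "read_labels",
    "write_maps",
    "read_maps",
]

_AFFINE = np.eye(4)


def sidecar_path(image_path) -> Path:
    p = Path(image_path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def _atomic_save(img: nib.Nifti1Image, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".nii.gz")
    os.close(fd)
    try:
        nib.save(img, tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".json")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_multiecho(volume, echo_times, path, extra_meta: dict | None = None
                    ) -> Path:
    """Write a 4-D multi-echo volume plus its echo-time sidecar."""
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim != 4:
        raise ValueError(f"expected 4-D volume, got {vol.ndim}-D")
    tes = echo_times if isinstance(echo_times, EchoTimes) else EchoTimes(
        np.asarray(echo_times, float))
    if len(tes) != vol.shape[-1]:
        raise ValueError(f"{len(tes)} echo times for {vol.shape[-1]} echoes")
    path = Path(path)
    _atomic_save(nib.Nifti1Image(vol, _AFFINE), path)
    meta = {"EchoTimesMs": list(map(float, tes.values))}
    meta.update(extra_meta or {})
    _atomic_json(meta, sidecar_path(path))
    return path


def read_multiecho(path, echo_times=None) -> tuple[np.ndarray, EchoTimes]:
    """Load a 4-D multi-echo NIfTI and its echo times.

    Echo times come from ``echo_times`` if given, else the JSON sidecar
    (key ``EchoTimesMs``).  The count must match the 4th dimension and
    the times must be ascending.
    """
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim != 4:
        raise ValueError(
            f"{path}: expected a 4-D multi-echo image, got {vol.ndim}-D; "
            "pass echo times explicitly for reshaped data")
    if echo_times is None:
        sc = sidecar_path(path)
        if not sc.exists():
            raise ValueError(f"{path}: no echo times given and no sidecar "
                             f"{sc.name} found")
        with open(sc) as fh:
            meta = json.load(fh)
        if "EchoTimesMs" not in meta:
            raise ValueError(f"{sc}: sidecar lacks 'EchoTimesMs'")
        echo_times = meta["EchoTimesMs"]
    tes = EchoTimes(np.asarray(echo_times, dtype=float))
    if len(tes) != vol.shape[-1]:
        raise ValueError(f"{path}: {vol.shape[-1]} echo volumes but "
                         f"{len(tes)} echo times")
    return vol, tes


def write_labels(labels, path, names: dict[int, str] | None = None) -> Path:
    """Write an integer label mask; label->name mapping in the sidecar."""
    lab = np.asarray(labels)
    if not np.issubdtype(lab.dtype, np.integer):
        raise ValueError("label mask must be integer-valued")
    path = Path(path)
    _atomic_save(nib.Nifti1Image(lab.astype(np.int16), _AFFINE), path)
    if names:
        _atomic_json({"Labels": {str(k): v for k, v in names.items()}},
                     sidecar_path(path))
    return path


def read_labels(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(np.int16)


def write_maps(stack: MapStack, out_dir, provenance: dict | None = None
               ) -> dict[str, Path]:
    """Write every map of a stack as 3-D NIfTI plus validity and provenance.

    NaN sentinels at non-biexponential voxels are preserved as-is
    (floating NaN in the files).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in MapStack.MAP_NAMES:
        p = out / f"{name}.nii.gz"
        _atomic_save(nib.Nifti1Image(
            np.asarray(getattr(stack, name), dtype=np.float64), _AFFINE), p)
        written[name] = p
    for name, arr in (("validity", stack.validity.astype(np.uint8)),
                      ("model_code", stack.model_code)):
        p = out / f"{name}.nii.gz"
        _atomic_save(nib.Nifti1Image(arr, _AFFINE), p)
        written[name] = p
    prov = {"software": "t2biexp", "version": __version__}
    prov.update(provenance or {})
    _atomic_json(prov, out / "provenance.json")
    written["provenance"] = out / "provenance.json"
    return written


def read_maps(map_dir) -> MapStack:
    """Load a map stack previously written by :func:`write_maps`."""
    d = Path(map_dir)

    def load(name):
        return np.asarray(nib.load(str(d / f"{name}.nii.gz")).dataobj,
                          dtype=float)

    kwargs = {name: load(name) for name in MapStack.MAP_NAMES}
    kwargs["validity"] = load("validity").astype(bool)
    kwargs["model_code"] = load("model_code").astype(np.int8)
    return MapStack(**kwargs)
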