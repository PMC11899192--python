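"""Readers/writers and geometric bookkeeping for images, masks and tables.

Volumes travel as NIfTI-1 (image plus two mask volumes, spacing in the
header); single slices as 16-bit PNG/TIFF with a JSON sidecar carrying the
spacing (and, for phantoms, the ground truth). Covariate tables are CSV with
columns exactly ``subject_id, sex, age, bmi, mfi_class, sft``.

Masks are binarized with a ``> 0`` threshold on read, so {0, 255} and {0, 1}
encodings are equivalent. Anisotropic in-plane spacing is accepted here but
rejected later by morphometry, which assumes isotropy.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .errors import AlignmentError, InsufficientSlicesError, MetadataError
from .types import RoiMask, SliceImage, SubjectStack

__all__ = [
    "COVARIATE_COLUMNS",
    "write_subject_stack",
    "read_subject_stack",
    "write_slice_png",
    "read_slice_png",
    "read_covariates",
    "select_central_slices",
]

COVARIATE_COLUMNS = ["subject_id", "sex", "age", "bmi", "mfi_class", "sft"]

_IMG_SUFFIX = "_image.nii"
_BONE_SUFFIX = "_bone.nii"
_MARROW_SUFFIX = "_marrow.nii"


def _stack_to_volume(planes: list[np.ndarray]) -> np.ndarray:
    # rows -> y, cols -> x; NIfTI stores (x, y, z)
    return np.stack([p.T for p in planes], axis=-1)


def _volume_to_planes(vol: np.ndarray) -> list[np.ndarray]:
    return [vol[..., k].T for k in range(vol.shape[-1])]


def write_subject_stack(stack: SubjectStack, out_dir: str | Path) -> dict[str, Path]:
    """Write a subject's image and mask volumes as NIfTI-1 files.

    Returns the mapping of volume kind to path. Pixel spacing and the
    through-plane step (slice thickness + gap) go into the affine/zooms.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img0 = stack.slices[0][0]
    sy, sx = img0.pixel_spacing
    dz = img0.slice_thickness + img0.slice_gap
    affine = np.diag([sx, sy, dz, 1.0])

    paths = {}
    for kind, suffix, planes, dtype in (
        ("image", _IMG_SUFFIX, [s[0].values for s in stack.slices], np.float32),
        ("bone", _BONE_SUFFIX, [s[1].values for s in stack.slices], np.uint8),
        ("marrow", _MARROW_SUFFIX, [s[2].values for s in stack.slices], np.uint8),
    ):
        vol = _stack_to_volume([np.asarray(p, dtype=dtype) for p in planes])
        path = out_dir / f"{stack.subject_id}{suffix}"
        nib.save(nib.Nifti1Image(vol, affine), str(path))
        paths[kind] = path
    return paths


def _load_nifti(path: Path) -> tuple[list[np.ndarray], tuple[float, float], float]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    if len(zooms) < 3 or zooms[0] <= 0 or zooms[1] <= 0:
        raise MetadataError(f"{path}: NIfTI header lacks valid pixel spacing")
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise MetadataError(f"{path}: expected a 3D volume, got shape {data.shape}")
    # zooms are (x, y, z); planes are returned row=y, col=x
    return _volume_to_planes(data), (float(zooms[1]), float(zooms[0])), float(zooms[2])


def read_subject_stack(
    image_path: str | Path,
    bone_path: str | Path,
    marrow_path: str | Path,
    subject_id: str | None = None,
    covariates: dict | None = None,
    min_usable_slices: int = 7,
) -> SubjectStack:
    """Read a subject's NIfTI volumes into a validated :class:`SubjectStack`.

    Masks are binarized with ``> 0``. Slices whose bone mask is entirely
    empty are flagged and dropped; the subject is rejected when fewer than
    ``min_usable_slices`` usable slices remain.
    """
    image_path = Path(image_path)
    img_planes, spacing, dz = _load_nifti(image_path)
    bone_planes, bone_spacing, _ = _load_nifti(Path(bone_path))
    marrow_planes, marrow_spacing, _ = _load_nifti(Path(marrow_path))

    if not (len(img_planes) == len(bone_planes) == len(marrow_planes)):
        raise AlignmentError(
            f"slice counts differ: image {len(img_planes)}, "
            f"bone {len(bone_planes)}, marrow {len(marrow_planes)}"
        )
    for other, name in ((bone_spacing, "bone"), (marrow_spacing, "marrow")):
        if not np.allclose(other, spacing):
            raise AlignmentError(f"{name} mask spacing {other} != image spacing {spacing}")

    sid = subject_id or image_path.name.replace(_IMG_SUFFIX, "").replace(".gz", "")
    cov = covariates or {}
    slices = []
    for k, (ip, bp, mp) in enumerate(zip(img_planes, bone_planes, marrow_planes)):
        if ip.shape != bp.shape or ip.shape != mp.shape:
            raise AlignmentError(
                f"slice {k}: image shape {ip.shape} != mask shapes {bp.shape}/{mp.shape}"
            )
        if not (bp > 0).any():
            warnings.warn(f"subject {sid}: slice {k} has an empty bone mask; dropped",
                          stacklevel=2)
            continue
        img = SliceImage(values=ip, pixel_spacing=spacing, slice_index=k)
        bone = RoiMask(values=bp > 0, pixel_spacing=spacing, label="bone", slice_index=k)
        marrow = RoiMask(values=mp > 0, pixel_spacing=spacing, label="marrow", slice_index=k)
        slices.append((img, bone, marrow))

    if len(slices) < min_usable_slices:
        raise InsufficientSlicesError(
            f"subject {sid}: only {len(slices)} usable slices (< {min_usable_slices})"
        )
    return SubjectStack(
        subject_id=sid,
        slices=slices,
        age=cov.get("age"),
        sex=cov.get("sex"),
        bmi=cov.get("bmi"),
        mfi_class=cov.get("mfi_class"),
        sft=cov.get("sft"),
    )


def write_slice_png(
    image: SliceImage,
    path: str | Path,
    truth: dict | None = None,
) -> Path:
    """Write one slice as 16-bit PNG plus a JSON sidecar with the spacing.

    Intensities are mapped from [0, 1] to the full 16-bit range; the sidecar
    records the scale so the round trip is lossless to 1/65535.
    """
    path = Path(path)
    scaled = np.clip(image.values, 0.0, 1.0)
    iio.imwrite(path, (scaled * 65535).round().astype(np.uint16))
    sidecar = {
        "pixel_spacing": list(image.pixel_spacing),
        "slice_index": image.slice_index,
        "slice_thickness": image.slice_thickness,
        "slice_gap": image.slice_gap,
        "intensity_scale": 65535,
    }
    if truth:
        sidecar["truth"] = truth
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_slice_png(path: str | Path) -> SliceImage:
    """Read a PNG slice; spacing must come from the JSON sidecar."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise MetadataError(f"{path}: missing sidecar {sidecar_path.name} with pixel spacing")
    sidecar = json.loads(sidecar_path.read_text())
    if "pixel_spacing" not in sidecar:
        raise MetadataError(f"{sidecar_path}: sidecar lacks pixel_spacing")
    values = np.asarray(iio.imread(path), dtype=float) / sidecar.get("intensity_scale", 65535)
    return SliceImage(
        values=values,
        pixel_spacing=tuple(sidecar["pixel_spacing"]),
        slice_index=int(sidecar.get("slice_index", 0)),
        slice_thickness=float(sidecar.get("slice_thickness", 4.0)),
        slice_gap=float(sidecar.get("slice_gap", 2.0)),
    )


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the covariate CSV, enforcing the column contract."""
    df = pd.read_csv(path)
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"covariate table missing columns: {missing}")
    return df


def select_central_slices(stack, count: int = 7):
    """Keep the ``count`` slices centered on the middle of the stack.

    For 9 slices and count 7 this drops the first and last. With an even
    surplus the tie is broken toward the proximal (lower-index) side.
    Accepts a :class:`SubjectStack` (returns a new one) or a plain list of
    slice tuples (returns a sliced list).
    """
    if isinstance(stack, SubjectStack):
        slices = stack.slices
    else:
        slices = stack
    n = len(slices)
    if n < count:
        raise InsufficientSlicesError(f"{n} usable slices < requested {count}")
    start = (n - count) // 2  # floor -> proximal tie-break
    selected = slices[start : start + count]
    if isinstance(stack, SubjectStack):
        return SubjectStack(
            subject_id=stack.subject_id,
            slices=selected,
            age=stack.age,
            sex=stack.sex,
            bmi=stack.bmi,
            mfi_class=stack.mfi_class,
            sft=stack.sft,
        )
    return selected
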