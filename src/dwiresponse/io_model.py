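"""Core domain types and file I/O.

Images travel as NIfTI-1 volumes with the array axis order fixed as
``(x, y, slice)`` and all coordinates 0-based.  Diffusion weightings are
stored in a sidecar next to the image: either an FSL-style whitespace
separated ``.bval`` text file or a JSON file with a ``bvalues`` key (the
JSON form may additionally carry ``slice_thickness`` and ``slice_gap`` in
mm, which NIfTI headers cannot represent separately).  Cohort tables are
plain CSV with one row per animal.

ADC values are expressed in units of 1e-3 mm^2/s throughout; b-values in
s/mm^2.  The signal model is ``S(b) = S0 * exp(-b * ADC * 1e-3)``.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, ValidationError

GROUPS = ("therapy", "control")

#: Relative tolerance for cross-checking stored delta columns against
#: recomputation from the four base fields.
DELTA_RTOL = 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DWIStudy:
    """One imaging session: a stack of 3D magnitude volumes indexed by b-value.

    Parameters
    ----------
    volumes
        One 3D non-negative array per b-value, axis order (x, y, slice),
        identical shapes.
    bvalues
        Diffusion weightings in s/mm^2, strictly increasing and all > 0
        (the acquisition has no b=0 volume; the lowest weighting is 10).
    voxel_size
        In-plane spacing (mm), two entries.
    slice_thickness, slice_gap
        Through-plane geometry (mm); effective slice spacing is
        ``slice_thickness + slice_gap``.
    """

    volumes: list[np.ndarray]
    bvalues: list[float]
    voxel_size: tuple[float, float]
    slice_thickness: float
    slice_gap: float = 0.0
    study_id: str = ""

    def __post_init__(self) -> None:
        self.volumes = [np.asarray(v, dtype=float) for v in self.volumes]
        self.bvalues = [float(b) for b in self.bvalues]
        if len(self.volumes) != len(self.bvalues):
            raise ValidationError(
                f"{len(self.volumes)} volumes but {len(self.bvalues)} b-values"
            )
        if not self.volumes:
            raise ValidationError("study must contain at least one volume")
        shape = self.volumes[0].shape
        if any(v.ndim != 3 for v in self.volumes):
            raise ValidationError("every volume must be a 3D array")
        if any(v.shape != shape for v in self.volumes):
            raise ValidationError("all volumes must share identical dimensions")
        b = np.asarray(self.bvalues)
        if np.any(b <= 0):
            raise ValidationError("b-values must all be > 0")
        if np.any(np.diff(b) <= 0):
            raise ValidationError("b-values must be strictly increasing")
        vx, vy = self.voxel_size
        if vx <= 0 or vy <= 0 or self.slice_thickness <= 0:
            raise ValidationError("voxel_size and slice_thickness must be > 0")
        if self.slice_gap < 0:
            raise ValidationError("slice_gap must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    @property
    def n_bvalues(self) -> int:
        return len(self.bvalues)

    def stacked(self) -> np.ndarray:
        """Volumes as a 4D array (x, y, slice, b)."""
        return np.stack(self.volumes, axis=-1)


@dataclass
class ADCMap:
    """Voxelwise apparent diffusion coefficient map (1e-3 mm^2/s).

    ``valid`` flags voxels where the monoexponential fit converged; invalid
    voxels carry NaN in ``values``/``s0`` and are excluded from statistics.
    """

    values: np.ndarray
    s0: np.ndarray
    valid: np.ndarray
    voxel_size: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 1.0
    slice_gap: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.values.shape == self.s0.shape == self.valid.shape):
            raise ValidationError("values, s0 and valid must share dimensions")


@dataclass
class VOIMask:
    """Binary 3D tumor mask sharing a volume's geometry."""

    mask: np.ndarray
    voxel_size: tuple[float, float]
    slice_thickness: float
    slice_gap: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValidationError("mask must be a 3D array")
        uniq = np.unique(self.mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError("mask voxels must be strictly 0/1")
        self.mask = self.mask.astype(bool)
        vx, vy = self.voxel_size
        if vx <= 0 or vy <= 0 or self.slice_thickness <= 0:
            raise ValidationError("voxel_size and slice_thickness must be > 0")
        if self.slice_gap < 0:
            raise ValidationError("slice_gap must be >= 0")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class AnimalRecord:
    """Per-animal tumor summary for one baseline/follow-up pair.

    ``adc_b``/``adc_f`` are median tumor ADCs (1e-3 mm^2/s), ``vol_b``/``vol_f``
    tumor volumes (mm^3); ``d_adc = adc_f - adc_b`` and
    ``d_vol_pct = 100 * (vol_f - vol_b) / vol_b``.
    """

    animal_id: str
    group: str
    adc_b: float
    adc_f: float
    vol_b: float
    vol_f: float
    d_adc: float = None  # type: ignore[assignment]
    d_vol_pct: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group label {self.group!r}")
        if self.vol_b <= 0 or self.vol_f <= 0:
            raise ValidationError("volumes must be > 0")
        if self.adc_b <= 0 or self.adc_f <= 0:
            raise ValidationError("ADC values must be > 0")
        d_adc = self.adc_f - self.adc_b
        d_vol = 100.0 * (self.vol_f - self.vol_b) / self.vol_b
        for name, stored, recomputed in (
            ("d_adc", self.d_adc, d_adc),
            ("d_vol_pct", self.d_vol_pct, d_vol),
        ):
            if stored is not None and not math.isclose(
                stored, recomputed, rel_tol=DELTA_RTOL, abs_tol=DELTA_RTOL
            ):
                raise ConsistencyError(
                    f"{name}={stored} inconsistent with recomputed {recomputed}"
                )
        self.d_adc = d_adc
        self.d_vol_pct = d_vol


@dataclass
class CohortTable:
    """A two-group collection of :class:`AnimalRecord`."""

    records: list[AnimalRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.animal_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("animal_ids must be unique")

    def group(self, label: str) -> list[AnimalRecord]:
        if label not in GROUPS:
            raise ValidationError(f"unknown group label {label!r}")
        return [r for r in self.records if r.group == label]

    def column(self, name: str, group: str | None = None) -> np.ndarray:
        recs = self.records if group is None else self.group(group)
        return np.asarray([getattr(r, name) for r in recs], dtype=float)

    @property
    def group_counts(self) -> tuple[int, int]:
        return len(self.group("therapy")), len(self.group("control"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": [r.animal_id for r in self.records],
                "group": [r.group for r in self.records],
                "adc_b": [r.adc_b for r in self.records],
                "adc_f": [r.adc_f for r in self.records],
                "vol_b": [r.vol_b for r in self.records],
                "vol_f": [r.vol_f for r in self.records],
                "d_adc": [r.d_adc for r in self.records],
                "d_vol_pct": [r.d_vol_pct for r in self.records],
            }
        )


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def _read_bvalue_sidecar(path: str) -> tuple[list[float], float | None, float | None]:
    """Return (bvalues, slice_thickness, slice_gap); geometry entries may be None."""
    with open(path) as fh:
        text = fh.read()
    if os.path.splitext(path)[1].lower() == ".json":
        try:
            meta = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid JSON sidecar {path}: {exc}") from exc
        if "bvalues" not in meta:
            raise FormatError(f"JSON sidecar {path} lacks a 'bvalues' key")
        bvals = [float(b) for b in meta["bvalues"]]
        return bvals, meta.get("slice_thickness"), meta.get("slice_gap")
    try:
        bvals = [float(tok) for tok in text.split()]
    except ValueError as exc:
        raise FormatError(f"non-numeric entry in bval file {path}") from exc
    if not bvals:
        raise FormatError(f"empty bval file {path}")
    return bvals, None, None


def read_dwi_study(image_path: str, bvalue_path: str, study_id: str | None = None) -> DWIStudy:
    """Read a 4D NIfTI plus b-value sidecar into a :class:`DWIStudy`.

    Volumes are reordered to ascending b-value regardless of on-disk order.
    In-plane spacing comes from the NIfTI header; through-plane geometry
    from the JSON sidecar when present, otherwise the header slice spacing
    is taken as the thickness with zero gap.
    """
    img = nib.load(image_path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{image_path}: expected a 4D volume, got {data.ndim}D")
    bvals, thickness, gap = _read_bvalue_sidecar(bvalue_path)
    if data.shape[3] != len(bvals):
        raise FormatError(
            f"{image_path} has {data.shape[3]} volumes but sidecar lists {len(bvals)} b-values"
        )
    if len(set(bvals)) != len(bvals):
        raise ValidationError("duplicate b-values in sidecar")
    order = np.argsort(bvals)
    zooms = img.header.get_zooms()[:3]
    if gap is None:
        gap = 0.0
        if thickness is None:
            thickness = float(zooms[2])
    elif thickness is None:
        thickness = float(zooms[2]) - float(gap)
    return DWIStudy(
        volumes=[data[..., i] for i in order],
        bvalues=[bvals[i] for i in order],
        voxel_size=(float(zooms[0]), float(zooms[1])),
        slice_thickness=float(thickness),
        slice_gap=float(gap),
        study_id=study_id or os.path.basename(image_path),
    )


def _affine(voxel_size, slice_spacing) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], slice_spacing, 1.0])


def write_dwi_study(study: DWIStudy, image_path: str, bvalue_path: str) -> None:
    """Write a study as 4D NIfTI (float64) plus sidecar.

    A JSON sidecar preserves slice thickness and gap exactly; a ``.bval``
    sidecar stores only the b-values.
    """
    spacing = study.slice_thickness + study.slice_gap
    img = nib.Nifti1Image(study.stacked().astype(np.float64), _affine(study.voxel_size, spacing))
    img.header.set_zooms((*study.voxel_size, spacing, 1.0))
    nib.save(img, image_path)
    if os.path.splitext(bvalue_path)[1].lower() == ".json":
        with open(bvalue_path, "w") as fh:
            json.dump(
                {
                    "bvalues": study.bvalues,
                    "slice_thickness": study.slice_thickness,
                    "slice_gap": study.slice_gap,
                },
                fh,
                indent=1,
            )
    else:
        with open(bvalue_path, "w") as fh:
            fh.write(" ".join(repr(b) for b in study.bvalues) + "\n")


def read_voi_mask(path: str, slice_thickness: float | None = None,
                  slice_gap: float = 0.0) -> VOIMask:
    """Read a binary mask NIfTI; voxels must be strictly 0/1."""
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D mask, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if slice_thickness is None:
        slice_thickness = float(zooms[2]) - slice_gap
    return VOIMask(
        mask=data,
        voxel_size=(float(zooms[0]), float(zooms[1])),
        slice_thickness=slice_thickness,
        slice_gap=slice_gap,
    )


def write_voi_mask(mask: VOIMask, path: str) -> None:
    spacing = mask.slice_thickness + mask.slice_gap
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask.voxel_size, spacing))
    img.header.set_zooms((*mask.voxel_size, spacing))
    nib.save(img, path)


def write_adc_map(adc_map: ADCMap, path: str, sidecar_path: str | None = None,
                  provenance: dict | None = None) -> None:
    """Write an ADC map as float32 NIfTI (units 1e-3 mm^2/s) with an optional
    JSON provenance sidecar (b-values, fit bounds, registration settings)."""
    spacing = adc_map.slice_thickness + adc_map.slice_gap
    values = np.where(adc_map.valid, adc_map.values, np.nan).astype(np.float32)
    img = nib.Nifti1Image(values, _affine(adc_map.voxel_size, spacing))
    img.header.set_zooms((*adc_map.voxel_size, spacing))
    nib.save(img, path)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump({"units": "1e-3 mm^2/s", **(provenance or {})}, fh, indent=1)


# ---------------------------------------------------------------------------
# cohort table I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("animal_id", "group", "adc_b", "adc_f", "vol_b", "vol_f")


def _records_from_frame(df: pd.DataFrame, source: str) -> list[AnimalRecord]:
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for opt in ("d_adc", "d_vol_pct"):
            if opt in df.columns and pd.notna(row[opt]):
                kwargs[opt] = float(row[opt])
        records.append(
            AnimalRecord(
                animal_id=str(row["animal_id"]),
                group=str(row["group"]).strip().lower(),
                adc_b=float(row["adc_b"]),
                adc_f=float(row["adc_f"]),
                vol_b=float(row["vol_b"]),
                vol_f=float(row["vol_f"]),
                **kwargs,
            )
        )
    return records


def read_cohort_csv(path: str) -> CohortTable:
    """Read a per-animal cohort CSV.

    Required columns: animal_id, group, adc_b, adc_f, vol_b, vol_f.  Optional
    d_adc / d_vol_pct columns are cross-checked against recomputation from the
    base fields (relative tolerance 1e-6).  Numbers must use '.' as the
    decimal separator.
    """
    df = pd.read_csv(path)
    return CohortTable(records=_records_from_frame(df, path), provenance=str(path))


def write_cohort_csv(table: CohortTable, path: str) -> None:
    """Write the cohort with numerics at 12 significant digits (round-trip safe)."""
    df = table.to_frame()
    df.to_csv(path, index=False, float_format="%.12g")


def read_cohort_xlsx(path: str, sheet: int | str = 0) -> CohortTable:
    """Import a supplementary-table-style XLSX (one row per animal) with the
    same column layout as the cohort CSV."""
    df = pd.read_excel(path, sheet_name=sheet)
    df.columns = [str(c).strip().lower() for c in df.columns]
    return CohortTable(records=_records_from_frame(df, str(path)), provenance=str(path))
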