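"""Readers and writers for the package's plain-text data dialects.

Force curves: tab-separated values with ``# key: value`` comment headers
carrying probe and acquisition metadata (``k_N_per_m``, ``R_um``,
``condition``, ``animal``, ``time_h``, ...), columns ``z_um`` plus
``force_pN`` or ``deflection_nm``, optional ``segment`` and ``t_s``.
Masses and areas: RFC-4180 CSV.  All quantities convert to SI on read
and back to the human-scale units on write.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .contact import ProbeParameters
from .curves import RawForceCurve
from .errors import ConfigurationError, InvalidInputError
from .metrics import AreaSeries, MassRecord

__all__ = [
    "read_force_curve",
    "write_force_curve",
    "read_mass_records",
    "write_mass_records",
    "read_area_series",
    "write_area_series",
    "read_slice_image",
    "write_slice_image",
    "area_series_from_images",
    "write_manifest",
    "read_manifest",
]

_PROBE_KEYS = {"k_N_per_m", "R_um"}


def _parse_header(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" not in body:
                continue
            key, _, value = body.partition(":")
            value = value.strip()
            try:
                parsed: object = int(value)
            except ValueError:
                try:
                    parsed = float(value)
                except ValueError:
                    parsed = value
            meta[key.strip()] = parsed
    return meta


def read_force_curve(path: str | Path, probe: ProbeParameters | None = None) -> RawForceCurve:
    """Read one force curve from the TSV dialect.

    Probe parameters come from the header (``k_N_per_m``, ``R_um``)
    unless supplied explicitly.  A ``deflection_nm`` column is converted
    to force via the spring constant; this requires the spring constant
    to be known.
    """
    path = Path(path)
    meta = _parse_header(path)
    table = pd.read_csv(path, sep="\t", comment="#")
    if "z_um" not in table.columns:
        raise InvalidInputError(f"{path.name}: missing required column z_um")
    if probe is None:
        if "k_N_per_m" not in meta or "R_um" not in meta:
            raise ConfigurationError(
                f"{path.name}: header lacks k_N_per_m/R_um and no probe was supplied"
            )
        probe = ProbeParameters(
            tip_radius=float(meta["R_um"]) * 1e-6,
            spring_constant=float(meta["k_N_per_m"]),
        )
    z = table["z_um"].to_numpy(dtype=float) * 1e-6
    if "force_pN" in table.columns:
        force = table["force_pN"].to_numpy(dtype=float) * 1e-12
    elif "deflection_nm" in table.columns:
        force = table["deflection_nm"].to_numpy(dtype=float) * 1e-9 * probe.spring_constant
    else:
        raise InvalidInputError(f"{path.name}: need a force_pN or deflection_nm column")
    segment = table["segment"].to_numpy() if "segment" in table.columns else None
    time = table["t_s"].to_numpy(dtype=float) if "t_s" in table.columns else None
    metadata = {k: v for k, v in meta.items() if k not in _PROBE_KEYS}
    return RawForceCurve(
        piezo=z, force=force, probe=probe, segment=segment, time=time, metadata=metadata
    )


def write_force_curve(path: str | Path, curve: RawForceCurve) -> Path:
    """Write a force curve in the TSV dialect (force in pN)."""
    path = Path(path)
    cols = {"z_um": curve.piezo * 1e6, "force_pN": curve.force * 1e12}
    if curve.segment is not None:
        cols["segment"] = curve.segment
    if curve.time is not None:
        cols["t_s"] = curve.time
    with open(path, "w") as fh:
        fh.write("# slicemech force curve\n")
        fh.write(f"# k_N_per_m: {curve.probe.spring_constant!r}\n")
        fh.write(f"# R_um: {curve.probe.tip_radius * 1e6!r}\n")
        for key, value in sorted(curve.metadata.items()):
            fh.write(f"# {key}: {value}\n")
        pd.DataFrame(cols).to_csv(fh, sep="\t", index=False, float_format="%.8g")
    return path


def read_mass_records(path: str | Path) -> list[MassRecord]:
    """Read wet/dry mass records from CSV (animal_id, condition, time_h, wet_mg, dry_mg)."""
    table = pd.read_csv(path)
    required = {"animal_id", "condition", "time_h", "wet_mg", "dry_mg"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidInputError(f"mass CSV missing columns: {sorted(missing)}")
    return [
        MassRecord(
            wet_mass=float(row.wet_mg),
            dry_mass=float(row.dry_mg),
            condition=str(row.condition),
            time_h=float(row.time_h),
            animal_id=str(row.animal_id),
        )
        for row in table.itertuples()
    ]


def write_mass_records(path: str | Path, records: list[MassRecord]) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "condition": [r.condition for r in records],
            "time_h": [r.time_h for r in records],
            "wet_mg": [r.wet_mass for r in records],
            "dry_mg": [r.dry_mass for r in records],
        }
    ).to_csv(path, index=False)
    return path


def read_area_series(path: str | Path) -> list[AreaSeries]:
    """Read planar-area time series from CSV (animal_id, condition, time_h, area)."""
    table = pd.read_csv(path)
    required = {"animal_id", "condition", "time_h", "area"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidInputError(f"area CSV missing columns: {sorted(missing)}")
    out = []
    for (animal, condition), group in table.groupby(["animal_id", "condition"], sort=True):
        group = group.sort_values("time_h")
        out.append(
            AreaSeries(
                time_h=group["time_h"].to_numpy(dtype=float),
                planar_area=group["area"].to_numpy(dtype=float),
                condition=str(condition),
                animal_id=str(animal),
            )
        )
    return out


def write_area_series(path: str | Path, series: list[AreaSeries]) -> Path:
    path = Path(path)
    rows = []
    for s in series:
        for t, a in zip(s.time_h, s.planar_area):
            rows.append(
                {"animal_id": s.animal_id, "condition": s.condition, "time_h": t, "area": a}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_slice_image(path: str | Path, image: np.ndarray) -> Path:
    """Write a float image (0-1 range) as an 8-bit grayscale PNG/TIFF."""
    import imageio.v3 as iio

    path = Path(path)
    scaled = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (scaled * 255).round().astype(np.uint8))
    return path


def read_slice_image(path: str | Path) -> np.ndarray:
    """Read a slice photograph as a 2-D float array (channels averaged)."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    return img


def area_series_from_images(
    directory: str | Path, segment_fn, pattern: str = "*.png"
) -> list[AreaSeries]:
    """Build area series from image files named ``{animal}_{condition}_{time_h}h``.

    ``segment_fn`` maps a 2-D image array to a planar area (e.g.
    :func:`slicemech.metrics.segment_slice_area`).  Files whose names do
    not parse are skipped with a warning.
    """
    import logging

    rows: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for path in sorted(Path(directory).glob(pattern)):
        parts = path.stem.rsplit("_", 2)
        if len(parts) != 3 or not parts[2].endswith("h"):
            logging.getLogger(__name__).warning("unparseable image name: %s", path.name)
            continue
        animal, condition, time_part = parts
        try:
            time_h = float(time_part[:-1])
        except ValueError:
            logging.getLogger(__name__).warning("unparseable timepoint: %s", path.name)
            continue
        area = float(segment_fn(read_slice_image(path)))
        rows.setdefault((animal, condition), []).append((time_h, area))
    out = []
    for (animal, condition), samples in sorted(rows.items()):
        samples.sort()
        out.append(
            AreaSeries(
                time_h=np.array([t for t, _ in samples]),
                planar_area=np.array([a for _, a in samples]),
                condition=condition,
                animal_id=animal,
            )
        )
    return out


def write_manifest(path: str | Path, entries: list[dict], seed: int) -> Path:
    """Record generated outputs (paths relative to the manifest) and their seeds."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"seed": seed, "outputs": entries}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
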