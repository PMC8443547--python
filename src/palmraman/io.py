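"""Spectrum / feature-table data model and plain-text readers and writers.

The canonical on-disk format for a single spectrum is a two-column CSV
(wavenumber cm^-1, intensity counts) with ``#``-prefixed ``key=value``
header comments carrying sample metadata.  A minimal JCAMP-DX reader is
provided as a convenience for ``(X++(Y..Y))`` AFFN blocks.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "RipenessLabel",
    "Spectrum",
    "FEATURE_NAMES",
    "SUB_BANDS",
    "read_spectrum",
    "write_spectrum",
    "read_feature_table",
    "write_feature_table",
    "validate_feature_table",
]

#: The four overlapping components of the C=C stretching (nu1) band, in
#: ascending order of mean peak position.
SUB_BANDS = ("nu1a", "nu1b", "nu1c", "nu1d")

#: Fixed order of the 15 per-sample predictors: 4 sub-band positions,
#: 4 peak intensities, 3 intensity ratios (nu1b as numerator), 4 FWHM.
FEATURE_NAMES = (
    tuple(f"pos_{b}" for b in SUB_BANDS)
    + tuple(f"int_{b}" for b in SUB_BANDS)
    + ("ratio_b_a", "ratio_b_c", "ratio_b_d")
    + tuple(f"fwhm_{b}" for b in SUB_BANDS)
)

_REGIONS = ("top", "middle", "bottom")


class RipenessLabel(enum.IntEnum):
    """Ripeness class, ordered by maturity (UNDER_RIPE < RIPE < OVER_RIPE)."""

    UNDER_RIPE = 0
    RIPE = 1
    OVER_RIPE = 2

    @property
    def short(self) -> str:
        return ("UDR", "RP", "OVR")[int(self)]

    @classmethod
    def from_string(cls, text: str) -> "RipenessLabel":
        key = text.strip().upper().replace(" ", "_").replace("-", "_")
        aliases = {
            "UDR": cls.UNDER_RIPE,
            "RP": cls.RIPE,
            "OVR": cls.OVER_RIPE,
            "UNDER_RIPE": cls.UNDER_RIPE,
            "UNDERRIPE": cls.UNDER_RIPE,
            "RIPE": cls.RIPE,
            "OVER_RIPE": cls.OVER_RIPE,
            "OVERRIPE": cls.OVER_RIPE,
        }
        if key not in aliases:
            raise ValidationError(f"unknown ripeness label: {text!r}")
        return aliases[key]


@dataclass(frozen=True)
class Spectrum:
    """A single Raman spectrum on a strictly increasing wavenumber axis.

    Parameters
    ----------
    wavenumbers
        Raman shift axis in cm^-1, strictly increasing, all finite.
    intensities
        Scattering intensity in arbitrary counts, same length as the axis.
    sample_id
        Free-text sample identifier.
    region
        Optional fruitlet scan region, one of ``top``/``middle``/``bottom``.
    label
        Optional :class:`RipenessLabel`.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""
    region: str | None = None
    label: RipenessLabel | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1 or w.size != y.size:
            raise ValidationError("wavenumbers and intensities must be 1-D and equally long")
        if w.size < 2:
            raise ValidationError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(y))):
            raise ValidationError("spectrum contains non-finite values")
        order = np.argsort(w, kind="stable")
        w, y = w[order], y[order]
        if np.any(np.diff(w) <= 0):
            raise ValidationError("wavenumbers contain duplicates; axis must be strictly increasing")
        if self.region is not None and self.region not in _REGIONS:
            raise ValidationError(f"region must be one of {_REGIONS}, got {self.region!r}")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with replaced intensities (metadata kept)."""
        return replace(self, intensities=np.asarray(intensities, dtype=float))


# ---------------------------------------------------------------------------
# spectrum CSV


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a spectrum as a two-column CSV with ``# key=value`` header lines."""
    path = Path(path)
    lines = [f"# sample_id={spectrum.sample_id}"]
    if spectrum.region is not None:
        lines.append(f"# region={spectrum.region}")
    if spectrum.label is not None:
        lines.append(f"# label={spectrum.label.name}")
    for w, y in zip(spectrum.wavenumbers, spectrum.intensities):
        lines.append(f"{float(w)!r},{float(y)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _read_csv_spectrum(path: Path) -> tuple[list[float], list[float], dict]:
    meta: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
            continue
        parts = [p for p in line.replace(";", ",").split(",") if p.strip()]
        if len(parts) < 2:
            raise ParseError(f"{path}: line {lineno}: expected two comma-separated values")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric value ({exc})") from None
    return xs, ys, meta


def _read_jcamp_spectrum(path: Path) -> tuple[list[float], list[float], dict]:
    """Minimal JCAMP-DX reader for AFFN ``XYDATA=(X++(Y..Y))`` blocks.

    Compressed ordinate forms (SQZ/DIF/DUP) are not supported.
    """
    meta: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    xfactor = yfactor = 1.0
    deltax = None
    in_data = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XFACTOR":
                xfactor = float(value)
            elif key == "YFACTOR":
                yfactor = float(value)
            elif key == "DELTAX":
                deltax = float(value)
            elif key == "TITLE":
                meta["sample_id"] = value
            elif key == "XYDATA":
                if "X++(Y..Y)" not in value.replace(" ", ""):
                    raise ParseError(f"{path}: line {lineno}: unsupported XYDATA form {value!r}")
                in_data = True
            elif key == "END":
                in_data = False
            continue
        if not in_data:
            continue
        try:
            numbers = [float(tok) for tok in line.replace(",", " ").split()]
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric value ({exc})") from None
        if len(numbers) < 2:
            raise ParseError(f"{path}: line {lineno}: XYDATA line needs an X and at least one Y")
        x0, yvals = numbers[0], numbers[1:]
        if deltax is None:
            step = 1.0
        else:
            step = deltax
        for j, yv in enumerate(yvals):
            xs.append((x0 + j * step) * xfactor)
            ys.append(yv * yfactor)
    if not xs:
        raise ParseError(f"{path}: no XYDATA block found")
    return xs, ys, meta


def read_spectrum(path: str | Path, format: str | None = None) -> Spectrum:
    """Read a spectrum from CSV (default) or JCAMP-DX.

    The format is inferred from the extension (``.jdx``/``.dx``/``.jcamp``
    select JCAMP-DX) unless given explicitly.  The returned spectrum is
    sorted by ascending wavenumber.
    """
    path = Path(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in {".jdx", ".dx", ".jcamp"} else "csv"
    if format == "csv":
        xs, ys, meta = _read_csv_spectrum(path)
    elif format == "jcamp":
        xs, ys, meta = _read_jcamp_spectrum(path)
    else:
        raise ValidationError(f"unknown spectrum format: {format!r}")
    if len(xs) < 2:
        raise ParseError(f"{path}: fewer than 2 data rows")
    label = None
    if meta.get("label"):
        label = RipenessLabel.from_string(meta["label"])
    return Spectrum(
        wavenumbers=np.asarray(xs),
        intensities=np.asarray(ys),
        sample_id=meta.get("sample_id", path.stem),
        region=meta.get("region") or None,
        label=label,
    )


# ---------------------------------------------------------------------------
# feature table CSV

_TABLE_COLUMNS = ("sample_id", "label") + FEATURE_NAMES


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check column presence/order and finiteness of the 15 feature columns."""
    missing = [c for c in _TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"feature table is missing columns: {missing}")
    table = table.loc[:, list(_TABLE_COLUMNS)]
    feats = table.loc[:, list(FEATURE_NAMES)]
    if len(table) and not np.all(np.isfinite(feats.to_numpy(dtype=float))):
        raise ValidationError("feature table contains missing or non-finite feature values")
    return table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a feature table as CSV in the fixed column order.

    Labels are stored as their short codes (UDR/RP/OVR); a missing label is
    stored as an empty string.
    """
    path = Path(path)
    table = validate_feature_table(table).copy()
    table["label"] = [_label_to_string(lab) for lab in table["label"]]
    table.to_csv(path, index=False)
    return path


def _label_to_string(lab) -> str:
    # pandas may have coerced IntEnum labels to plain ints/floats
    if lab is None or (isinstance(lab, float) and np.isnan(lab)):
        return ""
    if isinstance(lab, str):
        return RipenessLabel.from_string(lab).short if lab else ""
    return RipenessLabel(int(lab)).short


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table CSV written by :func:`write_feature_table`."""
    raw = pd.read_csv(path, keep_default_na=False, dtype={"sample_id": str, "label": str})
    table = validate_feature_table(raw)
    table = table.copy()
    # explicit object dtype: pandas would otherwise coerce IntEnum to float
    table["label"] = pd.Series(
        [RipenessLabel.from_string(s) if s else None for s in table["label"]],
        index=table.index,
        dtype=object,
    )
    return table
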