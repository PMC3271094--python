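"""File formats and shared conventions for localization data and mesh measurements.

All geometry is continuous and in nanometres.  The origin sits at the
lower-left corner of the imaged region with y increasing upward.  Pixels
enter only at rendering: pixel (i, j) of a raster with pixel size p and
origin (x0, y0) has its centre at (x0 + p*(j + 0.5), y0 + p*(i + 0.5)),
where i indexes rows (y) and j columns (x).

On-disk formats are plain text: localization tables, mesh seeds and
measurement tables are UTF-8 CSV ('.' decimal, comma delimiter, '#'
comment lines carry provenance); scene configurations are YAML; raster
exports are 16-bit grayscale TIFF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
import yaml

#: canonical localization-table column names
X, Y, FRAME, PHOTONS, SIGMA = "x_nm", "y_nm", "frame", "photons", "sigma_nm"
LOCALIZATION_COLUMNS = [X, Y, FRAME, PHOTONS, SIGMA]

SEED_COLUMNS = ["label", "cx_nm", "cy_nm"]

#: fixed measurement-table column order (golden-file friendly)
MEASUREMENT_COLUMNS = [
    "label",
    "cx_nm",
    "cy_nm",
    "mean_radius_nm",
    "circumference_nm",
    "diameter_nm",
    "area_um2",
    "feret_ratio",
    "orientation_ratio",
    "on_strand_density_um2",
    "interior_density_um2",
    "band_area_um2",
    "interior_area_um2",
    "correction_offset_nm",
    "n_localizations_roi",
    "flags",
]


class TableFormatError(ValueError):
    """A delimited input file does not satisfy the declared dialect."""


@dataclass(frozen=True)
class LocalizationTable:
    """Ordered collection of single-molecule localization records.

    Wraps a DataFrame with the canonical columns ``x_nm, y_nm, frame,
    photons, sigma_nm``: position (nm), camera frame index, total signal
    photon count Q and per-molecule localization accuracy sigma (nm).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LOCALIZATION_COLUMNS if c not in self.df.columns]
        if missing:
            raise TableFormatError(f"missing required column(s): {missing}")
        object.__setattr__(self, "df", self.df[LOCALIZATION_COLUMNS].reset_index(drop=True))

    @classmethod
    def from_arrays(cls, x, y, frame=None, photons=None, sigma_loc=None) -> "LocalizationTable":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = x.size
        df = pd.DataFrame(
            {
                X: x,
                Y: y,
                FRAME: np.zeros(n, dtype=int) if frame is None else np.asarray(frame, dtype=int),
                PHOTONS: np.ones(n) if photons is None else np.asarray(photons, dtype=float),
                SIGMA: np.full(n, 1.0) if sigma_loc is None else np.asarray(sigma_loc, dtype=float),
            }
        )
        return cls(df)

    # -- column views -------------------------------------------------
    @property
    def x(self) -> np.ndarray:
        return self.df[X].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.df[Y].to_numpy(dtype=float)

    @property
    def xy(self) -> np.ndarray:
        return self.df[[X, Y]].to_numpy(dtype=float)

    @property
    def frame(self) -> np.ndarray:
        return self.df[FRAME].to_numpy()

    @property
    def photons(self) -> np.ndarray:
        return self.df[PHOTONS].to_numpy(dtype=float)

    @property
    def sigma_loc(self) -> np.ndarray:
        return self.df[SIGMA].to_numpy(dtype=float)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) bounding box of all records, nm."""
        if len(self) == 0:
            raise ValueError("empty table has no extent")
        x, y = self.x, self.y
        return float(x.min()), float(x.max()), float(y.min()), float(y.max())

    def __len__(self) -> int:
        return len(self.df)

    def select_box(self, xmin: float, xmax: float, ymin: float, ymax: float) -> "LocalizationTable":
        """Records with xmin <= x <= xmax and ymin <= y <= ymax."""
        m = (self.x >= xmin) & (self.x <= xmax) & (self.y >= ymin) & (self.y <= ymax)
        return LocalizationTable(self.df.loc[m])

    def validate(self) -> None:
        """Raise if any record violates the domain invariants."""
        if len(self) and not np.isfinite(self.xy).all():
            raise ValueError("non-finite coordinates")
        if len(self) and (self.sigma_loc <= 0).any():
            raise ValueError("sigma_nm must be > 0")
        if len(self) and (self.photons < 0).any():
            raise ValueError("photons must be >= 0")


# ---------------------------------------------------------------------------
# localization tables


def _coerce_numeric(raw: pd.DataFrame, source: str, canonical: str) -> pd.Series:
    vals = pd.to_numeric(raw[source], errors="coerce")
    bad = vals.isna()
    if bad.any():
        # +2: header line plus 1-based indexing
        rows = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())[:10]]
        raise TableFormatError(
            f"non-numeric or missing value(s) in column '{source}' "
            f"(mapped to '{canonical}') at file line(s) {rows}"
        )
    return vals


def read_localization_table(path, column_map: dict[str, str] | None = None) -> LocalizationTable:
    """Read a delimited localization table.

    ``column_map`` maps canonical names (``x_nm`` ...) to the headers
    actually present in the file; unmapped canonical names are looked up
    verbatim.  All five canonical columns are mandatory.
    """
    raw = pd.read_csv(path, comment="#")
    column_map = dict(column_map or {})
    out = {}
    for canonical in LOCALIZATION_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source not in raw.columns:
            raise TableFormatError(
                f"missing required column '{source}' (for '{canonical}'); "
                f"file has columns {list(raw.columns)}"
            )
        out[canonical] = _coerce_numeric(raw, source, canonical)
    df = pd.DataFrame(out)
    df[FRAME] = df[FRAME].astype(int)
    table = LocalizationTable(df)
    table.validate()
    return table


def write_localization_table(table: LocalizationTable, path, provenance: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        table.df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# mesh seeds


def read_mesh_seeds(path) -> pd.DataFrame:
    """Read approximate mesh centres: columns label, cx_nm, cy_nm."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SEED_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"seed file missing column(s): {missing}")
    for c in ("cx_nm", "cy_nm"):
        df[c] = _coerce_numeric(df, c, c)
    return df[SEED_COLUMNS]


def write_mesh_seeds(seeds: pd.DataFrame, path, provenance: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        seeds[SEED_COLUMNS].to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# measurement tables


def validate_measurements(df: pd.DataFrame) -> None:
    """Check the per-mesh invariants: d = C/pi, feret in (0,1], densities >= 0."""
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"measurement table missing column(s): {missing}")
    c = df["circumference_nm"].to_numpy(dtype=float)
    d = df["diameter_nm"].to_numpy(dtype=float)
    ok = np.isfinite(c) & np.isfinite(d)
    if ok.any():
        rel = np.abs(d[ok] - c[ok] / np.pi) / np.maximum(np.abs(d[ok]), 1e-300)
        if (rel > 1e-9).any():
            raise TableFormatError("diameter_nm != circumference_nm / pi")
    fr = df["feret_ratio"].to_numpy(dtype=float)
    fr = fr[np.isfinite(fr)]
    if ((fr <= 0) | (fr > 1 + 1e-12)).any():
        raise TableFormatError("feret_ratio outside (0, 1]")
    for col in ("on_strand_density_um2", "interior_density_um2"):
        v = df[col].to_numpy(dtype=float)
        if (v[np.isfinite(v)] < 0).any():
            raise TableFormatError(f"{col} must be >= 0")


def write_measurement_table(df: pd.DataFrame, path, provenance: str | None = None) -> None:
    validate_measurements(df)
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df[MEASUREMENT_COLUMNS].to_csv(fh, index=False)


def read_measurement_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    validate_measurements(df)
    return df[MEASUREMENT_COLUMNS]


# ---------------------------------------------------------------------------
# rasters and configs


def write_tiff(data: np.ndarray, path, vmax: float | None = None, description: str | None = None) -> None:
    """Export a raster as 16-bit grayscale TIFF.

    The in-memory convention puts row 0 at the bottom (y up); TIFF rows run
    top-down, so the array is flipped on export.  Intensities are scaled
    linearly so that ``vmax`` (default: the data maximum) maps to 65535.
    """
    data = np.asarray(data, dtype=float)
    top = vmax if vmax is not None else (data.max() if data.size else 1.0)
    if top <= 0:
        top = 1.0
    scaled = np.clip(data / top, 0.0, 1.0) * 65535.0
    tifffile.imwrite(path, np.flipud(scaled).astype(np.uint16), description=description or "")


def read_frame_stack(path) -> np.ndarray:
    """Read a multi-page grayscale TIFF as a (frames, rows, cols) float array."""
    arr = tifffile.imread(path).astype(float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise TableFormatError(f"expected a 2D/3D grayscale stack, got shape {arr.shape}")
    return arr


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
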