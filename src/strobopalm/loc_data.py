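"""Domain types and delimited-text I/O for single-molecule localization tables.

A localization table is the universal input of the pipeline: one row per
detected single-molecule emission event, with the frame index, position,
photon count, background level and localization precision.  Internally all
lengths are nanometres and all times milliseconds; file dialects convert at
the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "NOISE_LABEL",
    "Localization",
    "LocalizationTable",
    "AcquisitionSettings",
    "Dialect",
    "THUNDERSTORM_DIALECT",
    "read_localizations",
    "write_localizations",
    "LocalizationFormatError",
]

#: Cluster label assigned to rows not belonging to any density cluster.
NOISE_LABEL = -1

#: Canonical internal column order.
_COLUMNS = ("frame", "x_nm", "y_nm", "photons", "background", "sigma_nm")


class LocalizationFormatError(ValueError):
    """Raised when a localization file violates the declared dialect."""


@dataclass(frozen=True)
class Localization:
    """A single detected emission event.

    Attributes
    ----------
    frame : int
        Zero-based acquisition frame index.
    x_nm, y_nm : float
        Position in nanometres (continuous point coordinates, not pixels).
    photons : float
        Detected photon count (>= 0).
    background : float
        Background photons per pixel (>= 0).
    sigma_nm : float
        Localization precision, 1 s.d. in nanometres (> 0).
    """

    frame: int
    x_nm: float
    y_nm: float
    photons: float = 0.0
    background: float = 0.0
    sigma_nm: float = 15.0

    def __post_init__(self) -> None:
        if self.frame < 0 or int(self.frame) != self.frame:
            raise ValueError(f"frame must be a non-negative integer, got {self.frame!r}")
        if not np.isfinite([self.x_nm, self.y_nm]).all():
            raise ValueError("coordinates must be finite")
        if self.sigma_nm <= 0:
            raise ValueError(f"sigma_nm must be > 0, got {self.sigma_nm!r}")
        if self.photons < 0 or self.background < 0:
            raise ValueError("photons and background must be >= 0")


class LocalizationTable:
    """Ordered collection of localizations backed by a pandas DataFrame.

    An optional per-row integer ``cluster_label`` column marks density-cluster
    membership; :data:`NOISE_LABEL` (= -1) means unassigned/noise.
    """

    def __init__(self, df: pd.DataFrame | None = None, *, validate: bool = True):
        if df is None:
            df = pd.DataFrame({c: pd.Series(dtype=float) for c in _COLUMNS})
            df["frame"] = df["frame"].astype(np.int64)
        df = df.reset_index(drop=True)
        if validate:
            self._validate(df)
        self._df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise LocalizationFormatError(f"missing required column(s): {', '.join(missing)}")
        if len(df) == 0:
            return
        frames = df["frame"].to_numpy()
        if not np.issubdtype(frames.dtype, np.integer):
            if not np.all(frames == np.floor(frames)):
                bad = int(np.flatnonzero(frames != np.floor(frames))[0])
                raise LocalizationFormatError(
                    f"non-integer frame index at row {bad}: {frames[bad]!r}"
                )
            df["frame"] = frames.astype(np.int64)
        if (df["frame"] < 0).any():
            raise LocalizationFormatError("negative frame index")
        if (df["sigma_nm"] <= 0).any():
            bad = int(df.index[df["sigma_nm"] <= 0][0])
            raise LocalizationFormatError(f"non-positive sigma_nm at row {bad}")
        coords = df[["x_nm", "y_nm"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise LocalizationFormatError("non-finite coordinate")
        if "cluster_label" in df.columns:
            labels = df["cluster_label"].to_numpy()
            if not np.all(labels == np.floor(labels)):
                raise LocalizationFormatError("cluster labels must be integers")
            if (labels < NOISE_LABEL).any():
                raise LocalizationFormatError(
                    f"cluster labels must be >= {NOISE_LABEL} (noise sentinel)"
                )
            df["cluster_label"] = labels.astype(np.int64)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        frame: np.ndarray,
        x_nm: np.ndarray,
        y_nm: np.ndarray,
        photons: np.ndarray | float = 0.0,
        background: np.ndarray | float = 0.0,
        sigma_nm: np.ndarray | float = 15.0,
        cluster_label: np.ndarray | None = None,
    ) -> "LocalizationTable":
        n = len(frame)
        data = {
            "frame": np.asarray(frame, dtype=np.int64),
            "x_nm": np.asarray(x_nm, dtype=float),
            "y_nm": np.asarray(y_nm, dtype=float),
            "photons": np.broadcast_to(np.asarray(photons, dtype=float), (n,)).copy(),
            "background": np.broadcast_to(np.asarray(background, dtype=float), (n,)).copy(),
            "sigma_nm": np.broadcast_to(np.asarray(sigma_nm, dtype=float), (n,)).copy(),
        }
        df = pd.DataFrame(data)
        if cluster_label is not None:
            df["cluster_label"] = np.asarray(cluster_label, dtype=np.int64)
        return cls(df)

    @classmethod
    def from_localizations(cls, locs: "list[Localization]") -> "LocalizationTable":
        df = pd.DataFrame([vars(l) for l in locs], columns=list(_COLUMNS))
        if len(locs) == 0:
            return cls()
        return cls(df)

    # -- accessors --------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def has_labels(self) -> bool:
        return "cluster_label" in self._df.columns

    def positions(self) -> np.ndarray:
        """(n, 2) array of x/y coordinates in nm."""
        return self._df[["x_nm", "y_nm"]].to_numpy(dtype=float)

    def with_labels(self, labels: np.ndarray) -> "LocalizationTable":
        df = self._df.copy()
        df["cluster_label"] = np.asarray(labels, dtype=np.int64)
        return LocalizationTable(df)

    def sorted_by_frame(self) -> "LocalizationTable":
        return LocalizationTable(
            self._df.sort_values("frame", kind="stable").reset_index(drop=True),
            validate=False,
        )

    def __len__(self) -> int:
        return len(self._df)

    def __getitem__(self, i: int) -> Localization:
        row = self._df.iloc[i]
        return Localization(
            frame=int(row["frame"]),
            x_nm=float(row["x_nm"]),
            y_nm=float(row["y_nm"]),
            photons=float(row["photons"]),
            background=float(row["background"]),
            sigma_nm=float(row["sigma_nm"]),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LocalizationTable):
            return NotImplemented
        if self.has_labels != other.has_labels:
            return False
        cols = list(_COLUMNS) + (["cluster_label"] if self.has_labels else [])
        if len(self) != len(other):
            return False
        return bool(
            np.allclose(
                self._df[cols].to_numpy(dtype=float),
                other._df[cols].to_numpy(dtype=float),
                rtol=0,
                atol=1e-9,
            )
        )


@dataclass(frozen=True)
class AcquisitionSettings:
    """Camera timing of a strobed (time-lapse) acquisition.

    ``tau_int_ms`` is the camera integration (exposure) time and ``tau_tl_ms``
    the frame period (time-lapse interval); continuous illumination is
    ``tau_tl_ms == tau_int_ms``.
    """

    tau_int_ms: float
    tau_tl_ms: float
    n_frames: int = 10_000

    def __post_init__(self) -> None:
        if not (self.tau_int_ms > 0):
            raise ValueError("tau_int_ms must be > 0")
        if self.tau_tl_ms < self.tau_int_ms:
            raise ValueError("tau_tl_ms must be >= tau_int_ms")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def duty_cycle(self) -> float:
        return self.tau_int_ms / self.tau_tl_ms

    @property
    def span_ms(self) -> float:
        return self.n_frames * self.tau_tl_ms


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping and unit scaling for a localization text file.

    ``columns`` maps canonical names (``frame``, ``x_nm``, ...) to the header
    names in the file; ``scale`` gives a multiplicative factor applied on read
    (e.g. 1000 for coordinates stored in micrometres) per canonical column.
    """

    columns: Mapping[str, str]
    scale: Mapping[str, float] = field(default_factory=dict)
    sep: str = ","

    def file_column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


#: ThunderSTORM-style header, the de-facto community interchange format.
THUNDERSTORM_DIALECT = Dialect(
    columns={
        "frame": "frame",
        "x_nm": "x [nm]",
        "y_nm": "y [nm]",
        "photons": "intensity [photon]",
        "background": "bkgstd [photon]",
        "sigma_nm": "uncertainty [nm]",
    }
)

_LABEL_COLUMN = "cluster_label"


def read_localizations(
    path: str | Path, dialect: Dialect = THUNDERSTORM_DIALECT
) -> LocalizationTable:
    """Read a delimited-text localization table.

    Unknown columns are ignored; a ``cluster_label`` column, when present, is
    carried through.  Raises :class:`LocalizationFormatError` on a missing
    mapped column and a parse error naming the offending row on non-numeric
    cells.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=dialect.sep)
    data: dict[str, np.ndarray] = {}
    for canonical in _COLUMNS:
        col = dialect.file_column(canonical)
        if col not in raw.columns:
            raise LocalizationFormatError(
                f"{path.name}: missing column {col!r} (mapped to {canonical!r})"
            )
        values = pd.to_numeric(raw[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(values) & raw[col].notna().to_numpy())
        if bad.size:
            raise LocalizationFormatError(
                f"{path.name}: non-numeric value {raw[col].iloc[bad[0]]!r} "
                f"in column {col!r} at data row {int(bad[0])}"
            )
        if np.isnan(values).any():
            raise LocalizationFormatError(
                f"{path.name}: empty cell in column {col!r}"
            )
        values = values * float(dialect.scale.get(canonical, 1.0))
        data[canonical] = values
    df = pd.DataFrame(data)
    if _LABEL_COLUMN in raw.columns:
        df[_LABEL_COLUMN] = pd.to_numeric(raw[_LABEL_COLUMN]).to_numpy()
    return LocalizationTable(df)


def write_localizations(
    table: LocalizationTable, path: str | Path, dialect: Dialect = THUNDERSTORM_DIALECT
) -> None:
    """Write a table as delimited text; rows are sorted by frame on write.

    Round-trips with :func:`read_localizations` under the same dialect
    (unit scaling is inverted on write).
    """
    table = table.sorted_by_frame()
    out = pd.DataFrame()
    for canonical in _COLUMNS:
        values = table.df[canonical].to_numpy(dtype=float)
        values = values / float(dialect.scale.get(canonical, 1.0))
        col = dialect.file_column(canonical)
        if canonical == "frame":
            out[col] = values.astype(np.int64)
        else:
            out[col] = values
    if table.has_labels:
        out[_LABEL_COLUMN] = table.df[_LABEL_COLUMN].to_numpy()
    out.to_csv(path, sep=dialect.sep, index=False, float_format="%.6f")
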