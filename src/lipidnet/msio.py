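"""Spectrum and feature-table I/O: MGF in/out, CSV feature tables.

MGF is the interchange format for MS/MS spectra (one BEGIN IONS/END IONS
block per spectrum, PEPMASS/RTINSECONDS/CHARGE/TITLE headers).  Retention
times are seconds in MGF but minutes everywhere inside the package.  Feature
tables are CSV with at least (feature_id, mz, rt) columns plus arbitrary
per-sample intensity columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

__all__ = [
    "Peak", "Spectrum", "FeatureTable",
    "read_mgf", "write_mgf", "read_feature_table", "link_spectra",
    "MZ_TOL_DA_LOW", "MZ_TOL_PPM_HIGH", "MZ_TOL_CROSSOVER", "RT_TOL_MIN",
]

# Piecewise m/z tolerance convention used for feature/spectrum pairing:
# absolute below the crossover, ppm above it.
MZ_TOL_DA_LOW = 0.005     # Da, for m/z < 500
MZ_TOL_PPM_HIGH = 10.0    # ppm, for m/z >= 500
MZ_TOL_CROSSOVER = 500.0  # Da
RT_TOL_MIN = 0.1          # minutes, MS/MS-to-feature pairing


def mz_tolerance(mz: float) -> float:
    """Absolute pairing tolerance (Da) at a given m/z."""
    if mz < MZ_TOL_CROSSOVER:
        return MZ_TOL_DA_LOW
    return mz * MZ_TOL_PPM_HIGH * 1e-6


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum.

    Peaks are held as parallel numpy arrays sorted by ascending m/z;
    duplicate m/z values are merged on construction (summed intensity).
    ``rt`` is in minutes and may be None when the source lacked it.
    """

    id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    rt: float | None = None
    charge: int = -1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.mz <= 0) or np.any(self.intensity < 0):
            raise ValueError("peaks must have positive m/z, non-negative intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        # merge exact-duplicate m/z values
        if self.mz.size > 1 and np.any(np.diff(self.mz) == 0):
            uniq, inverse = np.unique(self.mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inverse, self.intensity)
            self.mz, self.intensity = uniq, summed
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def is_usable(self) -> bool:
        """Whether the spectrum can participate in networking/matching."""
        return self.n_peaks > 0

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    @classmethod
    def from_peaks(cls, id: str, precursor_mz: float,
                   peaks: Iterable[tuple[float, float]], **kwargs) -> "Spectrum":
        arr = np.asarray(list(peaks), dtype=float).reshape(-1, 2)
        return cls(id=id, precursor_mz=precursor_mz,
                   mz=arr[:, 0], intensity=arr[:, 1], **kwargs)


class MGFError(ValueError):
    """Malformed MGF input (carries the offending block/line when known)."""


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    RTINSECONDS is converted to minutes; spectra lacking it get ``rt=None``.
    Empty peak lists are accepted (``is_usable`` is False for them).
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    try:
        with _mgf.MGF(str(path), convert_arrays=1) as reader:
            for i, entry in enumerate(reader):
                params = entry.get("params", {})
                pepmass = params.get("pepmass")
                if pepmass is None:
                    raise MGFError(f"block {i} in {path}: missing PEPMASS")
                rt = params.get("rtinseconds")
                charge = -1
                if params.get("charge"):
                    charge = int(params["charge"][0])
                spectra.append(Spectrum(
                    id=str(params.get("title", f"scan_{i}")),
                    precursor_mz=float(pepmass[0]),
                    mz=entry.get("m/z array", np.empty(0)),
                    intensity=entry.get("intensity array", np.empty(0)),
                    rt=float(rt) / 60.0 if rt is not None else None,
                    charge=charge,
                ))
    except MGFError:
        raise
    except Exception as exc:  # pyteomics raises various parse errors
        raise MGFError(f"malformed MGF {path}: {exc}") from exc
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF (m/z and intensity at full float precision)."""
    records = []
    for s in spectra:
        params = {"title": s.id, "pepmass": s.precursor_mz,
                  "charge": f"{abs(s.charge)}{'-' if s.charge < 0 else '+'}"}
        if s.rt is not None:
            params["rtinseconds"] = s.rt * 60.0
        records.append({"params": params,
                        "m/z array": s.mz, "intensity array": s.intensity})
    _mgf.write(records, str(path), write_charges=False,
               fragment_format="%.6f %.8g", file_mode="w")


@dataclass
class FeatureTable:
    """An aligned LC-MS feature table with optional spectrum links."""

    df: pd.DataFrame
    spectrum_ids: dict[str, list[str]] = field(default_factory=dict)

    REQUIRED_COLUMNS = ("feature_id", "mz", "rt")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        if self.df["feature_id"].duplicated().any():
            dupes = self.df.loc[self.df["feature_id"].duplicated(), "feature_id"]
            raise ValueError(f"duplicate feature ids: {sorted(set(dupes))}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_columns(self) -> list[str]:
        return [c for c in self.df.columns
                if c not in self.REQUIRED_COLUMNS and c != "spectrum_ids"]


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature CSV with mandatory (feature_id, mz, rt) columns."""
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip() for c in df.columns]
    table = FeatureTable(df=df)
    table.df["feature_id"] = table.df["feature_id"].astype(str)
    return table


def link_spectra(table: FeatureTable, spectra: Sequence[Spectrum],
                 rt_tol: float = RT_TOL_MIN) -> FeatureTable:
    """Pair MS/MS spectra with features by precursor m/z and retention time.

    A spectrum links to a feature when the precursor is within the piecewise
    m/z tolerance (0.005 Da below m/z 500, 10 ppm above) and the retention
    times agree within ``rt_tol`` minutes; spectra without a retention time
    match on m/z alone.
    """
    links: dict[str, list[str]] = {fid: [] for fid in table.df["feature_id"]}
    for spec in spectra:
        if not spec.is_usable:
            continue
        tol = mz_tolerance(spec.precursor_mz)
        for fid, fmz, frt in zip(table.df["feature_id"], table.df["mz"],
                                 table.df["rt"]):
            if abs(spec.precursor_mz - fmz) > tol:
                continue
            if spec.rt is not None and not np.isnan(frt):
                if abs(spec.rt - frt) > rt_tol:
                    continue
            links[fid].append(spec.id)
    return FeatureTable(df=table.df.copy(), spectrum_ids=links)
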