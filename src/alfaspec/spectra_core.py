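"""Core data structures and I/O for mid-infrared transmission spectra.

The conventions here mirror a bench FTIR workflow for ground forage samples
pressed into KBr pellets: spectra live on a wavenumber axis stored in
descending order (4000 -> 400 cm^-1, the instrument's native presentation),
each sample is the average of repeated scans, and intensities are either
percent transmittance or absorbance.  Absorbance is the working mode for
calibration because Beer-Lambert linearity in analyte concentration holds
there; conversion helpers are provided and round-trip exactly.

Canonical interchange formats are plain CSV: a wide spectra matrix
(``wavenumber_cm-1`` column followed by one column per sample) and a
two-column reference table (``sample_id,cp_percent``).  A minimal read-only
JCAMP-DX importer handles uncompressed single-spectrum exports.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TRANSMITTANCE = "transmittance_percent"
ABSORBANCE = "absorbance"
_MODES = (TRANSMITTANCE, ABSORBANCE)

DEFAULT_AXIS_START = 4000.0
DEFAULT_AXIS_END = 400.0
DEFAULT_N_POINTS = 10_329
DEFAULT_CP_RANGE = (9.00, 22.04)


class SpectraError(ValueError):
    """Raised for malformed spectra, axes or reference tables."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly monotone wavenumber grid in cm^-1.

    Stored descending by convention (instrument order); loaders re-sort
    ascending input.  ``values`` is an immutable float array.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise SpectraError("axis needs at least 2 wavenumber points")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise SpectraError("wavenumbers must be finite and positive")
        d = np.diff(v)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise SpectraError("axis must be strictly monotone (no duplicates)")
        v = v.copy()
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def descending(self) -> bool:
        return bool(self.values[0] > self.values[-1])

    def nearest_index(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.values - wavenumber)))

    @staticmethod
    def linspace(
        start: float = DEFAULT_AXIS_START,
        end: float = DEFAULT_AXIS_END,
        n_points: int = DEFAULT_N_POINTS,
    ) -> "WavenumberAxis":
        return WavenumberAxis(np.linspace(start, end, n_points))


@dataclass(frozen=True)
class Spectrum:
    """One sample's intensity trace on a wavenumber axis."""

    axis: WavenumberAxis
    intensity: np.ndarray
    mode: str = ABSORBANCE
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise SpectraError(f"unknown intensity mode {self.mode!r}")
        y = np.asarray(self.intensity, dtype=float)
        if y.shape != (self.axis.n_points,):
            raise SpectraError(
                f"intensity length {y.size} does not match axis "
                f"({self.axis.n_points} points)"
            )
        y = y.copy()
        y.setflags(write=False)
        object.__setattr__(self, "intensity", y)


@dataclass(frozen=True)
class SpectraSet:
    """Sample x wavenumber matrix with optional aligned reference values.

    ``X`` has one row per sample; ``y`` holds crude-protein reference values
    in % dry matter (None until :func:`attach_references` joins them).
    """

    axis: WavenumberAxis
    X: np.ndarray
    sample_ids: tuple[str, ...]
    y: np.ndarray | None = None
    mode: str = ABSORBANCE
    cp_range: tuple[float, float] = DEFAULT_CP_RANGE
    metadata: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise SpectraError(f"unknown intensity mode {self.mode!r}")
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.axis.n_points:
            raise SpectraError("X must be n_samples x n_points")
        if len(self.sample_ids) != X.shape[0]:
            raise SpectraError("sample_ids length must match rows of X")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SpectraError("duplicate sample ids")
        X = X.copy()
        X.setflags(write=False)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if self.y is not None:
            y = np.asarray(self.y, dtype=float)
            if y.shape != (X.shape[0],):
                raise SpectraError("y length must match number of spectra")
            lo, hi = self.cp_range
            if np.any(y < lo) or np.any(y > hi):
                raise SpectraError(
                    f"reference values outside declared range [{lo}, {hi}]"
                )
            y = y.copy()
            y.setflags(write=False)
            object.__setattr__(self, "y", y)

    @property
    def n_samples(self) -> int:
        return int(self.X.shape[0])

    @property
    def n_points(self) -> int:
        return int(self.X.shape[1])

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.X[i], self.mode, self.sample_ids[i])

    def with_metadata(self, **items: str) -> "SpectraSet":
        meta = dict(self.metadata)
        meta.update({k: str(v) for k, v in items.items()})
        return replace(self, metadata=tuple(sorted(meta.items())))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_spectra_csv(path: str | os.PathLike, mode: str = TRANSMITTANCE) -> SpectraSet:
    """Read a wide spectra matrix CSV into a :class:`SpectraSet` (no references).

    Column 1 is the wavenumber axis; remaining column headers become sample
    ids.  Ascending axes are re-sorted to the descending convention with row
    pairing preserved.  Non-numeric cells raise with row/column location.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise SpectraError(f"{path}: need a wavenumber column plus >=1 sample column")
    if df.shape[0] < 2:
        raise SpectraError(f"{path}: need at least 2 wavenumber points")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        cells = df[col].to_numpy()
        try:
            # python float() is correctly rounded (pandas' fast parser is
            # not), which the write->read bit-identity contract needs
            values[:, j] = [float(v) for v in cells]
        except (TypeError, ValueError):
            for i, v in enumerate(cells):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise SpectraError(
                        f"{path}: non-numeric cell {v!r} at data row "
                        f"{i + 1}, column {col!r}"
                    ) from None
    wn = values[:, 0]
    if np.unique(wn).size != wn.size:
        raise SpectraError(f"{path}: duplicate wavenumbers in first column")
    order = np.argsort(-wn)  # descending convention
    wn = wn[order]
    X = values[order, 1:].T
    axis = WavenumberAxis(wn)
    return SpectraSet(axis=axis, X=X, sample_ids=tuple(df.columns[1:]), mode=mode)


def write_spectra_csv(sset: SpectraSet, path: str | os.PathLike) -> None:
    """Write the wide spectra matrix CSV (full float precision)."""
    df = pd.DataFrame(sset.X.T, columns=list(sset.sample_ids))
    df.insert(0, "wavenumber_cm-1", sset.axis.values)
    df.to_csv(path, index=False, float_format="%.17g")


def read_reference_csv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "cp_percent"}
    if not required.issubset(df.columns):
        raise SpectraError(f"{path}: reference table needs columns {sorted(required)}")
    return df


def write_reference_csv(sset: SpectraSet, path: str | os.PathLike) -> None:
    if sset.y is None:
        raise SpectraError("no reference values attached")
    pd.DataFrame({"sample_id": sset.sample_ids, "cp_percent": sset.y}).to_csv(
        path, index=False, float_format="%.17g"
    )


def attach_references(
    sset: SpectraSet, ref_table: pd.DataFrame | Mapping[str, float]
) -> SpectraSet:
    """Join reference CP values to spectra by sample id, aligned to row order.

    Every spectrum id must appear exactly once in the table; offenders are
    listed in the error.
    """
    if isinstance(ref_table, Mapping):
        table = {str(k): float(v) for k, v in ref_table.items()}
        counts = {k: 1 for k in table}
    else:
        ids = ref_table["sample_id"].astype(str)
        counts = ids.value_counts().to_dict()
        table = dict(zip(ids, ref_table["cp_percent"].astype(float)))
    dup = sorted(k for k, c in counts.items() if c > 1)
    if dup:
        raise SpectraError(f"duplicate reference ids: {dup}")
    missing = sorted(s for s in sset.sample_ids if s not in table)
    if missing:
        raise SpectraError(f"missing reference values for ids: {missing}")
    y = np.array([table[s] for s in sset.sample_ids], dtype=float)
    lo = min(float(np.min(y)), sset.cp_range[0])
    hi = max(float(np.max(y)), sset.cp_range[1])
    return replace(sset, y=y, cp_range=(lo, hi))


# ---------------------------------------------------------------------------
# Intensity-mode conversion
# ---------------------------------------------------------------------------

def transmittance_to_absorbance_values(t_percent: np.ndarray) -> np.ndarray:
    t = np.asarray(t_percent, dtype=float)
    if np.any(t <= 0):
        raise SpectraError("non-positive transmittance cannot be log-converted")
    return -np.log10(t / 100.0)


def absorbance_to_transmittance_values(a: np.ndarray) -> np.ndarray:
    return 100.0 * np.power(10.0, -np.asarray(a, dtype=float))


def transmittance_to_absorbance(spectrum: Spectrum) -> Spectrum:
    """A = -log10(T/100); requires transmittance mode with positive values."""
    if spectrum.mode != TRANSMITTANCE:
        raise SpectraError(f"expected {TRANSMITTANCE} input, got {spectrum.mode}")
    return Spectrum(
        spectrum.axis,
        transmittance_to_absorbance_values(spectrum.intensity),
        ABSORBANCE,
        spectrum.sample_id,
    )


def absorbance_to_transmittance(spectrum: Spectrum) -> Spectrum:
    """T = 100 * 10^(-A); inverse of :func:`transmittance_to_absorbance`."""
    if spectrum.mode != ABSORBANCE:
        raise SpectraError(f"expected {ABSORBANCE} input, got {spectrum.mode}")
    return Spectrum(
        spectrum.axis,
        absorbance_to_transmittance_values(spectrum.intensity),
        TRANSMITTANCE,
        spectrum.sample_id,
    )


def convert_mode(sset: SpectraSet, target_mode: str) -> SpectraSet:
    """Convert a whole set between transmittance and absorbance."""
    if target_mode not in _MODES:
        raise SpectraError(f"unknown intensity mode {target_mode!r}")
    if sset.mode == target_mode:
        return sset
    if target_mode == ABSORBANCE:
        X = transmittance_to_absorbance_values(sset.X)
    else:
        X = absorbance_to_transmittance_values(sset.X)
    return replace(sset, X=X, mode=target_mode)


# ---------------------------------------------------------------------------
# Replicate averaging
# ---------------------------------------------------------------------------

def average_replicates(
    spectra: Sequence[Spectrum], sample_id: str | None = None
) -> Spectrum:
    """Pointwise arithmetic mean of replicate scans of one sample.

    All replicates must share axis and mode.  The id defaults to the longest
    common prefix of the replicate ids (trailing separators stripped).
    """
    if len(spectra) == 0:
        raise SpectraError("need at least one spectrum to average")
    first = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.axis.values, first.axis.values):
            raise SpectraError("replicates have mismatched wavenumber axes")
        if s.mode != first.mode:
            raise SpectraError("replicates have mismatched intensity modes")
    mean = np.mean([s.intensity for s in spectra], axis=0)
    if sample_id is None:
        sample_id = os.path.commonprefix([s.sample_id for s in spectra]).rstrip("_-. ")
        if not sample_id:
            sample_id = first.sample_id
    return Spectrum(first.axis, mean, first.mode, sample_id)


# ---------------------------------------------------------------------------
# Minimal JCAMP-DX reader (uncompressed AFFN XYDATA only)
# ---------------------------------------------------------------------------

def read_jcamp(path: str | os.PathLike) -> Spectrum:
    """Read a single-spectrum JCAMP-DX file with ``(X++(Y..Y))`` AFFN data.

    Supports plain space/comma-delimited numeric tables only; SQZ/DIF/DUP
    compressed forms raise.  The y ordinate is mapped to transmittance or
    absorbance from ``##YUNITS``.
    """
    header: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("$$"):
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                val = val.strip()
                if key == "XYDATA":
                    if "(X++(Y..Y))" not in val.replace(" ", ""):
                        raise SpectraError(f"unsupported XYDATA form {val!r}")
                    in_data = True
                    continue
                if key == "END":
                    break
                header[key] = val
                in_data = False
                continue
            if in_data:
                toks = line.replace(",", " ").split()
                try:
                    nums = [float(t) for t in toks]
                except ValueError as exc:
                    raise SpectraError(
                        f"{path}: compressed or non-AFFN JCAMP data line {line!r}"
                    ) from exc
                ys.extend(nums[1:])  # first token is the line's X value
    for req in ("FIRSTX", "LASTX", "NPOINTS"):
        if req not in header:
            raise SpectraError(f"{path}: missing ##{req}=")
    npoints = int(float(header["NPOINTS"]))
    if len(ys) != npoints:
        raise SpectraError(
            f"{path}: NPOINTS={npoints} but {len(ys)} ordinates found"
        )
    yfactor = float(header.get("YFACTOR", 1.0))
    xs = np.linspace(float(header["FIRSTX"]), float(header["LASTX"]), npoints)
    yunits = header.get("YUNITS", "TRANSMITTANCE").upper()
    mode = ABSORBANCE if "ABSORBANCE" in yunits else TRANSMITTANCE
    y = np.asarray(ys, dtype=float) * yfactor
    if mode == TRANSMITTANCE and np.nanmax(y) <= 1.5:
        y = y * 100.0  # fractional transmittance convention
    order = np.argsort(-xs)
    title = header.get("TITLE", os.path.basename(os.fspath(path)))
    return Spectrum(WavenumberAxis(xs[order]), y[order], mode, title)
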