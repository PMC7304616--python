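"""Reading, windowing and normalising unit-resolution mass spectra.

A GC-MS run of one essential oil is collapsed upstream into a single mass
spectrum: intensity indexed by integer mass-to-charge ratio (m/z, in Th).
The model consumes a fixed window of that spectrum — m/z 50 to 250 inclusive,
201 channels — because fragments below 50 Th come mostly from odorless small
molecules (O2, N2, CO2) and high-m/z ions from compounds too heavy to be
volatile.  Each windowed spectrum is rescaled to [0, 1] by dividing by its own
maximum, so every row of the resulting matrix has maximum exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MZ_LO = 50
DEFAULT_MZ_HI = 250


class SpectraError(ValueError):
    """Invalid spectrum data or window."""


class ZeroSpectrumError(SpectraError):
    """A spectrum with no positive intensity cannot be normalised."""


class SpectraParseError(SpectraError):
    """A spectra file could not be parsed; the message cites the location."""


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # GC-MS unit-resolution convention; ties (x.5) round toward +inf.
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass(frozen=True)
class MassSpectrum:
    """One mass spectrum: strictly increasing integer m/z with intensities >= 0."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=int)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or inten.ndim != 1 or mz.shape != inten.shape:
            raise SpectraError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise SpectraError("m/z values must be strictly increasing")
        if np.any(inten < 0):
            raise SpectraError("intensities must be non-negative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    @classmethod
    def from_peaks(cls, mz, intensity) -> "MassSpectrum":
        """Build a spectrum from possibly unordered, non-integer peak readings.

        Non-integer m/z are rounded half-up to the nearest integer bin;
        readings falling into the same bin are summed.
        """
        bins = _round_half_up(mz)
        inten = np.asarray(intensity, dtype=float)
        if np.any(inten < 0):
            raise SpectraError("intensities must be non-negative")
        uniq, inverse = np.unique(bins, return_inverse=True)
        summed = np.zeros(uniq.size)
        np.add.at(summed, inverse, inten)
        return cls(uniq, summed)


def extract_mz_window(spectrum: MassSpectrum, lo: int, hi: int) -> np.ndarray:
    """Dense intensity vector over the integer grid lo..hi inclusive.

    Channel ``i`` holds the intensity at m/z ``lo + i``; m/z values absent
    from the spectrum yield 0 (fragment absence is informative, and the model
    needs a dense fixed-width matrix).
    """
    if lo > hi:
        raise SpectraError(f"invalid m/z window: lo={lo} > hi={hi}")
    out = np.zeros(hi - lo + 1)
    mask = (spectrum.mz >= lo) & (spectrum.mz <= hi)
    out[spectrum.mz[mask] - lo] = spectrum.intensity[mask]
    return out


def normalize_spectrum(v: np.ndarray, sample_id: str | None = None) -> np.ndarray:
    """Rescale to [0, 1] by dividing by the vector's maximum."""
    v = np.asarray(v, dtype=float)
    m = v.max(initial=0.0)
    if m <= 0:
        who = f" (sample {sample_id!r})" if sample_id is not None else ""
        raise ZeroSpectrumError(f"cannot normalise an all-zero spectrum{who}")
    return v / m


@dataclass
class SpectraMatrix:
    """Samples x m/z-channels intensity matrix, one row per essential oil."""

    sample_ids: list[str]
    channels: np.ndarray
    values: np.ndarray
    normalized: bool = field(default=True)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.channels = np.asarray(self.channels, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise SpectraError(f"duplicate sample ids: {dupes}")
        if self.values.shape != (len(self.sample_ids), self.channels.size):
            raise SpectraError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.channels.size} channels"
            )
        if np.any(self.values < 0):
            raise SpectraError("intensity matrix has negative entries")
        if self.normalized and self.values.size:
            row_max = self.values.max(axis=1)
            if not np.allclose(row_max, 1.0):
                bad = [self.sample_ids[i] for i in np.flatnonzero(~np.isclose(row_max, 1.0))]
                raise SpectraError(f"rows not max-normalised: {bad[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.channels)


def _spectra_from_records(records, lo, hi, normalize):
    ids, rows = [], []
    for sample_id, spectrum in records:
        if sample_id in ids:
            raise SpectraParseError(f"duplicate sample id {sample_id!r}")
        v = extract_mz_window(spectrum, lo, hi)
        if normalize:
            v = normalize_spectrum(v, sample_id)
        ids.append(sample_id)
        rows.append(v)
    return SpectraMatrix(ids, np.arange(lo, hi + 1), np.vstack(rows) if rows else
                         np.empty((0, hi - lo + 1)), normalized=normalize)


def _read_table_records(path):
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SpectraParseError(f"{path}: need a sample-id column plus m/z columns")
    id_col = df.columns[0]
    try:
        mz = np.array([int(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise SpectraParseError(f"{path}: non-integer m/z column header ({exc})") from None
    order = np.argsort(mz)
    for row_pos, (_, row) in enumerate(df.iterrows()):
        sample_id = str(row[id_col])
        vals = pd.to_numeric(row.iloc[1:], errors="coerce").to_numpy(dtype=float)
        if np.any(np.isnan(vals)):
            bad = df.columns[1:][np.isnan(vals)][0]
            raise SpectraParseError(
                f"{path}: non-numeric intensity in row {row_pos + 2} "
                f"(sample {sample_id!r}, m/z {bad})"
            )
        yield sample_id, MassSpectrum(mz[order], vals[order])


def _read_msp_records(path):
    """Minimal MSP-style reader: 'Name:', 'Num Peaks:', then 'mz intensity;' pairs."""
    name, n_peaks, peaks = None, None, []

    def finish(lineno):
        if name is None:
            return None
        if n_peaks is not None and len(peaks) != n_peaks:
            raise SpectraParseError(
                f"{path}: record {name!r} ending at line {lineno} declares "
                f"{n_peaks} peaks but has {len(peaks)}"
            )
        if not peaks:
            raise SpectraParseError(f"{path}: record {name!r} has no peaks")
        mz, inten = zip(*peaks)
        return name, MassSpectrum.from_peaks(np.array(mz), np.array(inten))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                rec = finish(lineno)
                if rec is not None:
                    yield rec
                name, n_peaks, peaks = None, None, []
                continue
            low = line.lower()
            if low.startswith("name:"):
                name = line.split(":", 1)[1].strip()
            elif low.startswith("num peaks:"):
                try:
                    n_peaks = int(line.split(":", 1)[1])
                except ValueError:
                    raise SpectraParseError(f"{path}: bad Num Peaks at line {lineno}") from None
            elif ":" in line and not line[0].isdigit():
                continue  # other MSP headers (Formula:, MW:, ...) are ignored
            else:
                for pair in line.replace(";", " ;").split(";"):
                    pair = pair.strip()
                    if not pair:
                        continue
                    parts = pair.replace(",", " ").split()
                    if len(parts) != 2:
                        raise SpectraParseError(f"{path}: malformed peak at line {lineno}: {pair!r}")
                    try:
                        peaks.append((float(parts[0]), float(parts[1])))
                    except ValueError:
                        raise SpectraParseError(
                            f"{path}: non-numeric peak at line {lineno}: {pair!r}"
                        ) from None
    rec = finish(lineno if name is not None else 0)
    if rec is not None:
        yield rec


def read_spectra(path, format: str = "table", lo: int = DEFAULT_MZ_LO,
                 hi: int = DEFAULT_MZ_HI, normalize: bool = True) -> SpectraMatrix:
    """Read spectra from a delimited table or MSP-style file into a matrix.

    Windowing (``lo``..``hi`` inclusive) and per-spectrum max-normalisation are
    applied while reading; normalisation uses the maximum of the *windowed*
    vector, matching how the 50-250 matrix is rescaled downstream.
    """
    if format == "table":
        records = _read_table_records(path)
    elif format == "msp":
        records = _read_msp_records(path)
    else:
        raise ValueError(f"unknown spectra format {format!r} (expected 'table' or 'msp')")
    return _spectra_from_records(records, lo, hi, normalize)


def write_spectra(matrix: SpectraMatrix, path) -> None:
    """Write the matrix as a delimited table readable by :func:`read_spectra`."""
    matrix.to_frame().to_csv(path)
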