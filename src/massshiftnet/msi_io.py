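"""Containers and I/O for MSI data and internal artifacts.

imzML (continuous and processed binary modes) is the open exchange format
used for whole datasets; single spectra round-trip through two-column CSV.
Internal artifacts (histograms, training sets, model checkpoints) live in a
single-file container: a zip of numpy arrays plus a JSON metadata block.
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class Spectrum:
    """One mass spectrum at a spot: sorted m/z (Da, z=1 assumed) + intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    spot_id: str = "0"
    coords: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1D arrays of equal length")
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.mz.size

    def copy(self) -> "Spectrum":
        return Spectrum(self.mz.copy(), self.intensity.copy(), self.spot_id, self.coords)


def _clean_spectrum_arrays(mz, intensity, spot_id: str):
    """Sort m/z, drop duplicate m/z samples, clamp negative intensities."""
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.size > 1 and np.any(np.diff(mz) < 0):
        logger.warning("spot %s: m/z array not sorted on disk; sorting", spot_id)
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
    if mz.size > 1:
        keep = np.concatenate([[True], np.diff(mz) > 0])
        if not keep.all():
            logger.warning("spot %s: %d duplicate m/z samples dropped", spot_id, int((~keep).sum()))
            mz, intensity = mz[keep], intensity[keep]
    n_neg = int(np.count_nonzero(intensity < 0))
    if n_neg:
        logger.warning("spot %s: %d negative intensities clamped to 0", spot_id, n_neg)
        intensity = np.maximum(intensity, 0.0)
    return mz, intensity


@dataclass
class MSIDataset:
    """Ordered collection of spectra sharing one declared mass range."""

    spectra: list[Spectrum]
    mass_range: tuple[float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.spot_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            raise ValueError("spot_ids must be unique")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]


def read_imzml(path) -> MSIDataset:
    """Read an imzML file (either binary mode) into an :class:`MSIDataset`.

    m/z arrays are sorted and negative intensities clamped on read, so the
    output always satisfies the Spectrum invariants.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise IOError(f"imzML file not found: {path}")
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # malformed XML, missing .ibd
        raise IOError(f"failed to parse imzML file {path}: {exc}") from exc

    spectra = []
    lo, hi = np.inf, -np.inf
    for i, coords in enumerate(parser.coordinates):
        mz, intensity = parser.getspectrum(i)
        spot_id = f"spot_{i}"
        mz, intensity = _clean_spectrum_arrays(mz, intensity, spot_id)
        if mz.size:
            lo, hi = min(lo, mz[0]), max(hi, mz[-1])
        spectra.append(Spectrum(mz, intensity, spot_id=spot_id, coords=(int(coords[0]), int(coords[1]))))
    if not spectra:
        raise IOError(f"imzML file contains no spectra: {path}")
    return MSIDataset(spectra=spectra, mass_range=(float(lo), float(hi)))


def write_imzml(dataset: MSIDataset, path, mode: str = "processed") -> None:
    """Write a dataset as imzML; continuous mode requires identical grids."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    if mode not in ("continuous", "processed"):
        raise ValueError(f"unknown imzML mode: {mode!r}")
    if len(dataset) == 0:
        raise ValueError("cannot write an empty dataset")
    if mode == "continuous":
        ref = dataset[0].mz
        for s in dataset:
            if len(s) != len(ref) or not np.array_equal(s.mz, ref):
                raise ValueError("continuous mode requires all spectra to share one m/z grid")
    with ImzMLWriter(str(path), mode=mode, spec_type="profile") as writer:
        for i, s in enumerate(dataset):
            coords = s.coords if s.coords is not None else (i + 1, 1)
            # imzML coordinates are 1-based
            x, y = int(coords[0]), int(coords[1])
            writer.addSpectrum(s.mz, s.intensity, (max(x, 1), max(y, 1), 1))


def read_spectrum_csv(path) -> Spectrum:
    """Read a two-column (m/z, intensity) CSV; header row optional."""
    path = Path(path)
    mz, intensity = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = [f.strip() for f in line.replace("\t", ",").split(",") if f.strip()]
            if len(fields) < 2:
                raise ValueError(f"{path}: row {lineno}: expected two columns, got {len(fields)}")
            try:
                m, i = float(fields[0]), float(fields[1])
            except ValueError:
                if lineno == 1:  # tolerate a header row
                    continue
                raise ValueError(f"{path}: row {lineno}: non-numeric value in {fields[:2]}") from None
            mz.append(m)
            intensity.append(i)
    if not mz:
        raise ValueError(f"{path}: no numeric rows found")
    mz_arr, int_arr = _clean_spectrum_arrays(np.array(mz), np.array(intensity), path.stem)
    return Spectrum(mz_arr, int_arr, spot_id=path.stem)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("mz,intensity\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{m:.9g},{i:.9g}\n")


# ---------------------------------------------------------------------------
# artifact container: numpy arrays + JSON metadata in one zip file


def save_artifact(path, arrays: dict[str, np.ndarray], meta: dict) -> None:
    """Write named arrays plus a JSON metadata block to a single file."""
    path = Path(path)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=2, sort_keys=True))
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.save(buf, np.asarray(arr), allow_pickle=False)
            zf.writestr(f"arrays/{name}.npy", buf.getvalue())


def load_artifact(path) -> tuple[dict[str, np.ndarray], dict]:
    path = Path(path)
    if not path.exists():
        raise IOError(f"artifact file not found: {path}")
    arrays: dict[str, np.ndarray] = {}
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        for name in zf.namelist():
            if name.startswith("arrays/") and name.endswith(".npy"):
                arrays[name[len("arrays/"):-4]] = np.load(io.BytesIO(zf.read(name)), allow_pickle=False)
    return arrays, meta
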