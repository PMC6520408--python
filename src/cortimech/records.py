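"""Raw measurement containers and their plain-text serialisation.

Every modality consumes one of these records:

* :class:`LoadDisplacementRecord` -- indentation and compression traces
  (time s, load N, displacement mm, optional second displacement channel,
  per-point segment labels such as ``load``/``hold``/``unload``).
* :class:`UltrasoundTrace` -- digitised through-transmission pulse.
* :class:`ResonanceSpectrum` -- detected resonant frequencies in kHz.
* :class:`CTVolume` -- grayscale voxel grid with physical voxel size.
* :class:`DensityRecord` -- repeated calliper and mass readings.

Tabular records round-trip through CSV with a units header row; volumes are
written as multi-page TIFF stacks with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LoadDisplacementRecord",
    "UltrasoundTrace",
    "ResonanceSpectrum",
    "CTVolume",
    "DensityRecord",
]


@dataclass
class LoadDisplacementRecord:
    """Timestamped load/displacement trace with segment labels.

    displacement is the primary channel; ``displacement2`` holds the second
    LVDT channel for compression tests (``None`` for indentation).
    """

    time: np.ndarray          # s
    load: np.ndarray          # N
    displacement: np.ndarray  # mm
    displacement2: np.ndarray | None = None  # mm, second LVDT channel
    segments: np.ndarray | None = None       # per-point string labels
    specimen_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        n = self.time.size
        if not (self.load.size == n and self.displacement.size == n):
            raise ValueError("time, load and displacement must share length")
        if self.displacement2 is not None:
            self.displacement2 = np.asarray(self.displacement2, dtype=float)
            if self.displacement2.size != n:
                raise ValueError("displacement channels of unequal length")
        if self.segments is not None:
            self.segments = np.asarray(self.segments, dtype=object)
            if self.segments.size != n:
                raise ValueError("segment labels of unequal length")

    def __len__(self) -> int:
        return self.time.size

    def segment(self, label: str) -> "LoadDisplacementRecord":
        """Sub-record of all points carrying the given segment label."""
        if self.segments is None:
            raise ValueError("record has no segment labels")
        m = self.segments == label
        return LoadDisplacementRecord(
            self.time[m], self.load[m], self.displacement[m],
            None if self.displacement2 is None else self.displacement2[m],
            self.segments[m], self.specimen_id)

    def to_csv(self, path: str | Path) -> None:
        cols = {"time": self.time, "load": self.load,
                "displacement": self.displacement}
        units = {"time": "s", "load": "N", "displacement": "mm"}
        if self.displacement2 is not None:
            cols["displacement2"] = self.displacement2
            units["displacement2"] = "mm"
        if self.segments is not None:
            cols["segment"] = self.segments
            units["segment"] = "-"
        df = pd.DataFrame(cols)
        df.columns = pd.MultiIndex.from_tuples(
            [(c, units[c]) for c in df.columns])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, specimen_id: str = "") -> "LoadDisplacementRecord":
        df = pd.read_csv(path, header=[0, 1])
        df.columns = df.columns.get_level_values(0)
        return cls(
            df["time"].to_numpy(float), df["load"].to_numpy(float),
            df["displacement"].to_numpy(float),
            df["displacement2"].to_numpy(float) if "displacement2" in df else None,
            df["segment"].to_numpy(object) if "segment" in df else None,
            specimen_id)


@dataclass
class UltrasoundTrace:
    """Digitised received pulse; sample 0 is the emission instant (t = 0)."""

    samples: np.ndarray
    sampling_rate: float  # Hz
    axis: int = 3         # propagation direction (specimen axis 1|2|3)
    emit_time: float = 0.0
    specimen_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.size < 64:
            raise ValueError("trace needs at least 64 samples")
        if self.axis not in (1, 2, 3):
            raise ValueError("axis must be 1, 2 or 3")

    @property
    def times(self) -> np.ndarray:
        return self.emit_time + np.arange(self.samples.size) / self.sampling_rate

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({("time", "s"): self.times,
                           ("amplitude", "a.u."): self.samples})
        df.to_csv(path, index=False)


@dataclass
class ResonanceSpectrum:
    """Ascending resonant frequencies (kHz) with per-mode quality flags."""

    frequencies: np.ndarray  # kHz, sorted ascending
    flags: np.ndarray | None = None  # True = usable mode
    specimen_id: str = ""

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(self.frequencies) < 0):
            raise ValueError("frequencies must be sorted ascending")
        if self.flags is None:
            self.flags = np.ones(self.frequencies.size, dtype=bool)
        else:
            self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_modes(self) -> int:
        return int(self.frequencies.size)

    def usable(self) -> np.ndarray:
        return self.frequencies[self.flags]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({("frequency", "kHz"): self.frequencies,
                      ("usable", "bool"): self.flags}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResonanceSpectrum":
        df = pd.read_csv(path, header=[0, 1])
        df.columns = df.columns.get_level_values(0)
        flags = df["usable"].to_numpy(bool) if "usable" in df else None
        return cls(df["frequency"].to_numpy(float), flags)


@dataclass
class CTVolume:
    """Grayscale micro-CT voxel grid.

    Grid axes are (x, y, z) with grid axis 2 (z) aligned with specimen
    axis 3 (the osteonal direction).  ``voxel_size`` is isotropic, in
    micrometres.  ``true_pore_mask`` carries the generator's ground-truth
    labels when the volume is synthetic.
    """

    voxels: np.ndarray        # 3-D grayscale
    voxel_size: float         # um, isotropic
    sample_mask: np.ndarray | None = None
    specimen_id: str = ""
    true_pore_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.sample_mask is None:
            self.sample_mask = np.ones(self.voxels.shape, dtype=bool)
        else:
            self.sample_mask = np.asarray(self.sample_mask, dtype=bool)
            if self.sample_mask.shape != self.voxels.shape:
                raise ValueError("sample_mask shape mismatch")
        if not self.sample_mask.any():
            raise ValueError("sample_mask is empty")

    def to_tiff(self, path: str | Path) -> None:
        """Write a multi-page TIFF stack (pages along grid axis 2) plus a
        JSON sidecar ``<path>.json`` with the voxel size."""
        import tifffile
        path = Path(path)
        tifffile.imwrite(path, np.moveaxis(self.voxels, 2, 0))
        sidecar = {"voxel_size_um": self.voxel_size,
                   "specimen_id": self.specimen_id,
                   "axis_convention": "grid axis 2 = specimen axis 3"}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "CTVolume":
        import tifffile
        path = Path(path)
        voxels = np.moveaxis(tifffile.imread(path), 0, 2)
        meta = json.loads(Path(str(path) + ".json").read_text())
        return cls(voxels, meta["voxel_size_um"],
                   specimen_id=meta.get("specimen_id", ""))


@dataclass
class DensityRecord:
    """Repeated calliper and mass readings for one specimen.

    Four calliper repeats per axis (mm), eight wet-mass readings (mg, four
    before and four after the resonance measurement) and the post-furnace
    ash mass (mg).
    """

    calliper_mm: np.ndarray  # shape (3, 4): axis x repeat
    masses_mg: np.ndarray    # shape (8,)
    ash_mass_mg: float | None = None
    specimen_id: str = ""

    def __post_init__(self):
        self.calliper_mm = np.asarray(self.calliper_mm, dtype=float)
        self.masses_mg = np.asarray(self.masses_mg, dtype=float)
        if self.calliper_mm.shape != (3, 4):
            raise ValueError("expected 4 calliper repeats per axis (shape (3, 4))")
        if self.masses_mg.shape != (8,):
            raise ValueError("expected 8 wet-mass readings")
        if np.any(self.calliper_mm <= 0) or np.any(self.masses_mg <= 0):
            raise ValueError("all readings must be positive")
        if self.ash_mass_mg is not None and self.ash_mass_mg <= 0:
            raise ValueError("ash mass must be positive")
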