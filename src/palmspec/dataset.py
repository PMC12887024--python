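"""Spectral dataset container and delimited-text I/O.

A :class:`SpectralDataset` bundles a shared wavenumber grid, one intensity
row per oil sample, sample identifiers, market-of-origin labels and the
wet-chemistry reference table (peroxide value in meq O2/kg, iodine value in
g I2/100 g). Everything round-trips through two CSV files plus a JSON
manifest so runs are reproducible from plain text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Column names of the reference table, in file order.
REFERENCE_COLUMNS = ("sample_id", "market", "pv", "iv")


def make_wavenumber_grid(n_points: int = 1024, lo: float = 500.0, hi: float = 2000.0) -> np.ndarray:
    """Evenly spaced Raman-shift grid in cm^-1, endpoints included.

    Defaults match a 500-2000 cm^-1 scan digitised on 1024 channels.

    Parameters
    ----------
    n_points : int
        Number of channels, at least 2.
    lo, hi : float
        First and last wavenumber (cm^-1), ``lo < hi``.
    """
    if not isinstance(n_points, (int, np.integer)) or n_points < 2:
        raise ValueError(f"n_points must be an integer >= 2, got {n_points!r}")
    if not lo < hi:
        raise ValueError(f"need lo < hi, got lo={lo}, hi={hi}")
    return np.linspace(float(lo), float(hi), int(n_points))


@dataclass
class SpectralDataset:
    """Wavenumber grid + intensity matrix + per-sample metadata.

    Attributes
    ----------
    wavenumbers : ndarray, shape (p,)
        Strictly increasing Raman shifts in cm^-1.
    intensities : ndarray, shape (n, p)
        One spectrum per row, arbitrary intensity units.
    sample_ids : list of str
    markets : list of str
        Market-of-origin label per sample.
    reference : DataFrame
        Indexed by sample_id with columns ``pv`` and ``iv``.
    metadata : dict
        Free-form provenance (generator config, preprocessing applied, seed).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    markets: list[str]
    reference: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be 1-D and strictly increasing")
        n, p = self.intensities.shape
        if p != self.wavenumbers.size:
            raise ValueError(
                f"intensity row length {p} does not match grid length {self.wavenumbers.size}"
            )
        if not (len(self.sample_ids) == len(self.markets) == n):
            raise ValueError("sample_ids, markets and intensity rows must align")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def y(self, parameter: str) -> np.ndarray:
        """Reference vector for ``parameter`` ('PV' or 'IV'), aligned to rows."""
        key = parameter.lower()
        if key not in ("pv", "iv"):
            raise ValueError(f"parameter must be 'PV' or 'IV', got {parameter!r}")
        return self.reference.loc[self.sample_ids, key].to_numpy(dtype=float)

    def subset(self, indices: Sequence[int]) -> "SpectralDataset":
        """New dataset restricted to the given sample rows (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        ids = [self.sample_ids[i] for i in idx]
        return SpectralDataset(
            wavenumbers=self.wavenumbers.copy(),
            intensities=self.intensities[idx].copy(),
            sample_ids=ids,
            markets=[self.markets[i] for i in idx],
            reference=self.reference.loc[ids].copy(),
            metadata=dict(self.metadata),
        )

    def copy(self) -> "SpectralDataset":
        return self.subset(range(self.n_samples))

    # ------------------------------------------------------------------ I/O

    def to_csv(self, directory: str | Path) -> None:
        """Write ``spectra.csv``, ``reference.csv`` and ``manifest.json``.

        ``spectra.csv`` has columns sample_id, market, then one column per
        wavenumber (header = the wavenumber value).
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        spec = pd.DataFrame(self.intensities, columns=[f"{w:.6f}" for w in self.wavenumbers])
        spec.insert(0, "market", self.markets)
        spec.insert(0, "sample_id", self.sample_ids)
        spec.to_csv(directory / "spectra.csv", index=False)

        ref = self.reference.loc[self.sample_ids].reset_index()
        ref.insert(1, "market", self.markets)
        ref.to_csv(directory / "reference.csv", index=False, columns=list(REFERENCE_COLUMNS))

        manifest = {"n_samples": self.n_samples, "n_channels": self.n_channels,
                    "metadata": _jsonable(self.metadata)}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def from_csv(cls, directory: str | Path) -> "SpectralDataset":
        directory = Path(directory)
        spec = pd.read_csv(directory / "spectra.csv")
        ref = pd.read_csv(directory / "reference.csv")
        wavenumbers = np.array([float(c) for c in spec.columns[2:]])
        metadata: dict = {}
        manifest_path = directory / "manifest.json"
        if manifest_path.exists():
            metadata = json.loads(manifest_path.read_text()).get("metadata", {})
        return cls(
            wavenumbers=wavenumbers,
            intensities=spec.iloc[:, 2:].to_numpy(dtype=float),
            sample_ids=[str(s) for s in spec["sample_id"]],
            markets=[str(m) for m in spec["market"]],
            reference=ref.set_index("sample_id")[["pv", "iv"]].astype(float),
            metadata=metadata,
        )


def _jsonable(obj):
    """Best-effort conversion of nested config objects to JSON-serialisable form."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj
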