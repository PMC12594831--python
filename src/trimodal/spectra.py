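"""Chromophore absorption spectra.

Molar extinction coefficients for deoxy-hemoglobin (Hb), oxy-hemoglobin
(HbO2) and indocyanine green bound to plasma proteins (ICG), tabulated on the
near-infrared window used for multispectral photoacoustic imaging.  The
shipped table is a compilation of standard literature values (see the CSV
header); the package treats them as external constants.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

LN10 = float(np.log(10.0))

SPECIES = ("Hb", "HbO2", "ICG")


class SpectraTable:
    """Wavelength-indexed molar extinction table with linear interpolation.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``wavelength_nm`` (ascending) and ``eps_<species>`` for each
        species, units cm^-1 M^-1.
    """

    def __init__(self, table: pd.DataFrame):
        if "wavelength_nm" not in table.columns:
            raise ValueError("table must have a 'wavelength_nm' column")
        wl = np.asarray(table["wavelength_nm"], dtype=float)
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be ascending and unique")
        eps_cols = [c for c in table.columns if c.startswith("eps_")]
        if not eps_cols:
            raise ValueError("no eps_<species> columns found")
        eps = table[eps_cols].to_numpy(dtype=float)
        if np.any(eps < 0):
            raise ValueError("extinction coefficients must be non-negative")
        self.wavelengths_nm = wl
        self.species = tuple(c[len("eps_"):] for c in eps_cols)
        self._eps = {s: eps[:, i] for i, s in enumerate(self.species)}

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraTable":
        return cls(pd.read_csv(path, comment="#"))

    @classmethod
    def default(cls) -> "SpectraTable":
        """Table shipped with the package (660-900 nm, Hb/HbO2/ICG)."""
        with resources.files("trimodal.data").joinpath("chromophores.csv").open() as fh:
            return cls(pd.read_csv(fh, comment="#"))

    # -- queries -----------------------------------------------------------
    @property
    def coverage_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def _check_range(self, wavelength_nm):
        lo, hi = self.coverage_nm
        w = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
        if np.any(w < lo) or np.any(w > hi):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside table coverage "
                f"[{lo}, {hi}] nm; no extrapolation"
            )

    def epsilon(self, species: str, wavelength_nm) -> np.ndarray | float:
        """Molar extinction (cm^-1/M), linearly interpolated. No extrapolation."""
        if species not in self._eps:
            raise KeyError(f"unknown species {species!r}; have {self.species}")
        self._check_range(wavelength_nm)
        out = np.interp(np.asarray(wavelength_nm, dtype=float),
                        self.wavelengths_nm, self._eps[species])
        return float(out) if np.isscalar(wavelength_nm) else out

    def mua_mm(self, species: str, concentration_molar, wavelength_nm):
        """Absorption coefficient in mm^-1: ln(10) * eps * C / 10."""
        return LN10 * self.epsilon(species, wavelength_nm) * concentration_molar / 10.0

    def to_frame(self) -> pd.DataFrame:
        data = {"wavelength_nm": self.wavelengths_nm}
        for s in self.species:
            data[f"eps_{s}"] = self._eps[s]
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_table() -> SpectraTable:
    return SpectraTable.default()
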