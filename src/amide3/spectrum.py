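"""Core spectrum container."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class Spectrum:
    """A single absorbance trace on a wavenumber grid.

    Wavenumbers are canonicalized to strictly ascending order at construction
    (instrument exports are often descending).  Values must be finite and the
    two arrays equally long.

    Parameters
    ----------
    wavenumbers : array-like
        Wavenumber grid, cm^-1.
    absorbance : array-like
        Absorbance, arbitrary units, same length as `wavenumbers`.
    sample_id, portion_id : str | int | None
        Identity of the measured sample and of the portion (aliquot).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: str | None = None
    portion_id: int | None = None

    def __post_init__(self) -> None:
        nu = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if nu.ndim != 1 or ab.ndim != 1 or nu.size != ab.size:
            raise ValueError("wavenumbers and absorbance must be equal-length 1-D arrays")
        if nu.size == 0:
            raise ValueError("empty spectrum")
        if not (np.isfinite(nu).all() and np.isfinite(ab).all()):
            raise ValueError("spectrum contains non-finite values")
        order = np.argsort(nu, kind="stable")
        nu, ab = nu[order], ab[order]
        if np.any(np.diff(nu) <= 0):
            raise ValueError("duplicate wavenumbers in spectrum")
        object.__setattr__(self, "wavenumbers", nu)
        object.__setattr__(self, "absorbance", ab)

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def step(self) -> float:
        """Median grid step, cm^-1."""
        return float(np.median(np.diff(self.wavenumbers)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.wavenumbers)
        return bool(np.allclose(d, d[0], rtol=rtol))

    def with_absorbance(self, absorbance: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with a new absorbance trace on the same grid."""
        return replace(self, absorbance=np.asarray(absorbance, dtype=float))
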