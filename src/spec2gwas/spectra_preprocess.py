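"""Raw spectroradiometer frames -> one clean reflectance spectrum per sample.

The instrument records raw intensity frames together with a white-reference
frame (a Teflon tile with reflectance close to 100%) and a dark-current
frame.  Calibrated reflectance is

    I_cal = (I_raw - I_dark) / (I_white - I_dark)

band by band.  Low signal-to-noise bands below 400 nm and above 2450 nm are
trimmed, and the instrument's automatic repeat measurements (three per
sample by default) are averaged to a single spectrum per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "calibrate",
    "trim_bands",
    "average_replicates",
    "mean_spectrum",
]

#: Sanity bound on calibrated reflectance; beyond this the frames were
#: almost certainly passed in the wrong order.
_CAL_SANITY_BOUND = 10.0


@dataclass
class SpectraSet:
    """Sample x wavelength matrix of spectra with an optional replicate axis.

    Parameters
    ----------
    data:
        DataFrame whose columns are wavelengths in nm (float, strictly
        increasing) and whose index is either sample ids or a
        (sample, replicate) MultiIndex.
    role:
        One of ``{"raw", "white", "dark", "calibrated"}``.
    """

    data: pd.DataFrame
    role: str = "raw"

    def __post_init__(self) -> None:
        wl = np.asarray(self.data.columns, dtype=float)
        if wl.size == 0:
            raise ValueError("SpectraSet needs at least one wavelength band")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        self.data = self.data.copy()
        self.data.columns = wl
        if self.role not in {"raw", "white", "dark", "calibrated"}:
            raise ValueError(f"unknown frame role {self.role!r}")
        if self.role == "calibrated":
            vals = self.data.to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError("calibrated spectra must be finite")
            if np.any(np.abs(vals) > _CAL_SANITY_BOUND):
                raise ValueError(
                    "calibrated reflectance beyond sanity bound "
                    f"{_CAL_SANITY_BOUND}; frames likely mixed up"
                )

    # -- convenience accessors -------------------------------------------
    @property
    def wavelengths(self) -> np.ndarray:
        return np.asarray(self.data.columns, dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def samples(self) -> list:
        idx = self.data.index
        if isinstance(idx, pd.MultiIndex):
            return list(pd.unique(idx.get_level_values(0)))
        return list(idx)

    @property
    def has_replicates(self) -> bool:
        return isinstance(self.data.index, pd.MultiIndex)

    def band(self, wavelength: float) -> np.ndarray:
        """Reflectance column at the grid wavelength nearest `wavelength`."""
        wl = self.wavelengths
        j = int(np.argmin(np.abs(wl - wavelength)))
        return self.values[:, j]

    def __len__(self) -> int:
        return len(self.samples)


def _common_grid(*sets: SpectraSet) -> np.ndarray:
    grids = [s.wavelengths for s in sets]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise ValueError("all frames must share one wavelength grid")
    return grids[0]


def calibrate(raw: SpectraSet, white: SpectraSet, dark: SpectraSet) -> SpectraSet:
    """Convert raw intensity to reflectance with white/dark reference frames.

    ``I_cal = (I_raw - I_dark) / (I_white - I_dark)`` elementwise per band
    and replicate.  The white and dark frames are single spectra broadcast
    across all samples/replicates.

    Raises
    ------
    ZeroDivisionError
        If the white and dark frames coincide at any band (names the band).
    """
    wl = _common_grid(raw, white, dark)
    w = np.atleast_2d(white.values)
    d = np.atleast_2d(dark.values)
    if w.shape[0] != 1 or d.shape[0] != 1:
        raise ValueError("white and dark frames must each hold one spectrum")
    denom = (w - d)[0]
    bad = np.isclose(denom, 0.0)
    if np.any(bad):
        band = wl[np.argmax(bad)]
        raise ZeroDivisionError(
            f"white and dark frames coincide at {band:g} nm; cannot calibrate"
        )
    cal = (raw.values - d) / denom
    out = pd.DataFrame(cal, index=raw.data.index, columns=wl)
    return SpectraSet(out, role="calibrated")


def trim_bands(spectra: SpectraSet, low: float = 400.0, high: float = 2450.0) -> SpectraSet:
    """Drop low signal-to-noise edge bands, keeping ``low <= lambda <= high``."""
    if not low < high:
        raise ValueError("low must be < high")
    wl = spectra.wavelengths
    keep = (wl >= low) & (wl <= high)
    if not keep.any():
        raise ValueError(f"no bands remain in [{low}, {high}] nm")
    return SpectraSet(spectra.data.loc[:, spectra.data.columns[keep]], role=spectra.role)


def average_replicates(spectra: SpectraSet, policy: str = "strict") -> SpectraSet:
    """Average the instrument's repeat measurements per sample, band-wise.

    ``policy="strict"`` (default) rejects missing replicate values;
    ``policy="ignore-missing"`` averages over what is present.
    """
    if not spectra.has_replicates:
        return SpectraSet(spectra.data.copy(), role=spectra.role)
    vals = spectra.values
    if policy == "strict" and not np.all(np.isfinite(vals)):
        raise ValueError("missing replicate values (use policy='ignore-missing')")
    grouped = spectra.data.groupby(level=0, sort=False).mean()
    return SpectraSet(grouped, role=spectra.role)


def mean_spectrum(spectra: SpectraSet) -> pd.DataFrame:
    """Cross-sample mean and SD curves plus a mean +/- 3 SD envelope.

    SD uses the n-1 denominator.  Returns a DataFrame indexed by wavelength
    with columns ``mean, sd, lower, upper``.
    """
    vals = spectra.values
    if vals.shape[0] < 2:
        raise ValueError("need >= 2 samples for an SD curve")
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    return pd.DataFrame(
        {"mean": mu, "sd": sd, "lower": mu - 3 * sd, "upper": mu + 3 * sd},
        index=pd.Index(spectra.wavelengths, name="wavelength_nm"),
    )
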