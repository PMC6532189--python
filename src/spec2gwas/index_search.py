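"""Exhaustive two-band spectral-index construction and selection.

Three index families are searched over all wavelength pairs of a trimmed
reflectance grid:

    SRI  = R_a / R_b          (simple ratio)
    NDSI = (R_a - R_b) / (R_a + R_b)   (normalized difference)
    DSI  = R_a - R_b          (difference)

Each candidate index is scored by the squared Pearson correlation with the
trait across samples; the pair (and family) with the highest R^2 becomes
the "hyperspectral trait" used in place of the wet-lab measurement.

NDSI and DSI change only in sign under pair exchange, so they are searched
over unordered pairs in the canonical form lambda_a > lambda_b; SRI is not
correlation-invariant under inversion and is searched in both orders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra_preprocess import SpectraSet

__all__ = [
    "IndexDefinition",
    "IndexSearchEntry",
    "IndexSearchResults",
    "TwoBandIndexModel",
    "compute_index",
    "pearson_r2",
    "exhaustive_search",
    "select_hyperspectral_trait",
]

KINDS = ("SRI", "NDSI", "DSI")
#: Preference order used only to break exact R^2 ties between families.
_TIE_KIND_ORDER = {"NDSI": 0, "DSI": 1, "SRI": 2}


@dataclass(frozen=True)
class IndexDefinition:
    """One two-band index: family plus the (lambda_a, lambda_b) pair in nm."""

    kind: str
    lambda_a: float
    lambda_b: float

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown index kind {self.kind!r}")
        if self.lambda_a == self.lambda_b:
            raise ValueError("index needs two different wavelengths")

    @property
    def formula(self) -> str:
        a, b = f"R{self.lambda_a:g}", f"R{self.lambda_b:g}"
        if self.kind == "SRI":
            return f"{a}/{b}"
        if self.kind == "NDSI":
            return f"({a}-{b})/({a}+{b})"
        return f"{a}-{b}"


def compute_index(spectra: SpectraSet, defn: IndexDefinition) -> np.ndarray:
    """Per-sample values of one index; division guards yield NaN."""
    ra = spectra.band(defn.lambda_a)
    rb = spectra.band(defn.lambda_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        if defn.kind == "SRI":
            out = np.where(rb == 0, np.nan, ra / rb)
        elif defn.kind == "NDSI":
            s = ra + rb
            out = np.where(s == 0, np.nan, (ra - rb) / s)
        else:
            out = ra - rb
    return out


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation, pairwise-complete over non-missing pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(xc @ yc) / np.sqrt(sx * sy)
    return r * r


@dataclass
class IndexSearchEntry:
    """Best pair for one index family, with its R^2 and optional surface."""

    definition: IndexDefinition
    r2: float
    surface: pd.DataFrame | None = None

    @property
    def formula(self) -> str:
        return self.definition.formula


def _column_r2(values: np.ndarray, yc: np.ndarray, ynorm2: float) -> np.ndarray:
    """R^2 of each column of `values` with centered trait `yc` (no missing)."""
    vc = values - values.mean(axis=0)
    num = yc @ vc
    den2 = np.einsum("ij,ij->j", vc, vc) * ynorm2
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(den2 > 0, (num * num) / den2, np.nan)
    return r2


def _column_r2_masked(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pairwise-complete column-wise R^2 (slow path for missing values)."""
    out = np.full(values.shape[1], np.nan)
    for j in range(values.shape[1]):
        v = values[:, j]
        ok = np.isfinite(v)
        if ok.sum() < 3:
            continue
        try:
            out[j] = pearson_r2(v[ok], y[ok])
        except ValueError:
            continue
    return out


def exhaustive_search(
    spectra: SpectraSet,
    trait: pd.Series | np.ndarray,
    kind: str,
    keep_surface: bool = False,
    stride: int = 1,
) -> IndexSearchEntry:
    """Scan every admissible wavelength pair of one family for max R^2.

    The trait is aligned by sample id when given as a Series.  Ties break
    deterministically toward the smaller lambda_b, then smaller lambda_a.
    ``stride`` coarsens the grid for quick runs.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown index kind {kind!r}")
    R, y, wl = _align(spectra, trait)
    if stride > 1:
        R = R[:, ::stride]
        wl = wl[::stride]
    n, B = R.shape
    if n < 3:
        raise ValueError("need >= 3 aligned samples")
    clean = bool(np.all(np.isfinite(R)))
    yc = y - y.mean()
    ynorm2 = float(yc @ yc)
    if ynorm2 == 0:
        raise ValueError("trait has zero variance")

    surface = np.full((B, B), np.nan) if keep_surface else None
    best_r2 = -np.inf
    best_a = best_b = -1
    # loop over lambda_a (columns = candidate lambda_b)
    for ia in range(B):
        ra = R[:, ia : ia + 1]
        if kind == "SRI":
            cols = np.arange(B)
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = np.where(R[:, cols] == 0, np.nan, ra / R[:, cols])
        elif kind == "NDSI":
            cols = np.arange(ia)  # canonical lambda_a > lambda_b
            s = ra + R[:, cols]
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = np.where(s == 0, np.nan, (ra - R[:, cols]) / s)
        else:  # DSI
            cols = np.arange(ia)
            vals = ra - R[:, cols]
        if cols.size == 0:
            continue
        if clean and np.all(np.isfinite(vals)):
            r2s = _column_r2(vals, yc, ynorm2)
        else:
            r2s = _column_r2_masked(vals, y)
        if kind == "SRI":
            r2s[ia] = np.nan  # degenerate pair a == b
        if surface is not None:
            surface[ia, cols] = r2s
            if kind != "SRI":
                surface[cols, ia] = r2s  # mirrored half-surface
        finite = np.isfinite(r2s)
        if not finite.any():
            continue
        # deterministic tie-break: higher R2, then smaller lambda_b, then smaller lambda_a
        jb_local = int(np.flatnonzero(finite)[np.argmax(r2s[finite])])
        # np.argmax returns the first max, i.e. smallest lambda_b, since cols ascend
        cand = r2s[jb_local]
        jb = int(cols[jb_local])
        if cand > best_r2 or (
            cand == best_r2 and (jb, ia) < (best_b, best_a)
        ):
            best_r2, best_a, best_b = float(cand), ia, jb
    if best_a < 0:
        raise ValueError("no admissible pair produced a defined correlation")
    defn = IndexDefinition(kind, float(wl[best_a]), float(wl[best_b]))
    surf_df = (
        pd.DataFrame(surface, index=wl, columns=wl) if surface is not None else None
    )
    return IndexSearchEntry(defn, best_r2, surf_df)


def _align(spectra: SpectraSet, trait) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if spectra.has_replicates:
        raise ValueError("average replicates before the index search")
    wl = spectra.wavelengths
    if isinstance(trait, pd.Series):
        common = [s for s in spectra.samples if s in trait.index]
        if len(common) < 3:
            raise ValueError("fewer than 3 samples shared by spectra and trait")
        R = spectra.data.loc[common].to_numpy(dtype=float)
        y = trait.loc[common].to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
        if y.size != len(spectra):
            raise ValueError("trait length does not match sample count")
        R = spectra.values
    ok = np.isfinite(y)
    return R[ok], y[ok], wl


@dataclass
class IndexSearchResults:
    """Per-family best pairs plus the overall selection.

    Mirrors a fitted-model results object: ``entries`` maps family name to
    its :class:`IndexSearchEntry`; :meth:`selected` applies the highest-R^2
    rule; :meth:`hyperspectral_trait` returns the per-sample index values
    of the winner for downstream association testing.
    """

    entries: dict[str, IndexSearchEntry]
    spectra: SpectraSet | None = None
    trait_name: str = "trait"

    def selected(self) -> IndexSearchEntry:
        return select_hyperspectral_trait(self.entries)

    def hyperspectral_trait(self) -> pd.Series:
        if self.spectra is None:
            raise ValueError("results were built without spectra attached")
        entry = self.selected()
        vals = compute_index(self.spectra, entry.definition)
        return pd.Series(vals, index=self.spectra.samples, name=entry.definition.kind)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "trait": self.trait_name,
                "kind": kind,
                "lambda_a_nm": e.definition.lambda_a,
                "lambda_b_nm": e.definition.lambda_b,
                "formula": e.formula,
                "r2": e.r2,
                "selected": kind == self.selected().definition.kind,
            }
            for kind, e in self.entries.items()
        ]
        return pd.DataFrame(rows)


def select_hyperspectral_trait(entries: dict[str, IndexSearchEntry]) -> IndexSearchEntry:
    """Pick the family+pair with the globally highest R^2.

    Exact ties break by the declared family preference (NDSI, then DSI,
    then SRI) so the selection is deterministic.
    """
    if not entries:
        raise ValueError("no search results to select from")
    return min(
        entries.values(),
        key=lambda e: (-e.r2, _TIE_KIND_ORDER[e.definition.kind]),
    )


class TwoBandIndexModel:
    """Exhaustive two-band index search posed as a fittable model.

    Parameters
    ----------
    spectra:
        Calibrated, trimmed, replicate-averaged :class:`SpectraSet`.
    trait:
        Per-sample trait values (Series aligned by sample id, or array in
        spectra order).
    """

    def __init__(self, spectra: SpectraSet, trait, trait_name: str = "trait"):
        self.spectra = spectra
        self.trait = trait
        self.trait_name = (
            trait.name if isinstance(trait, pd.Series) and trait.name else trait_name
        )

    def fit(
        self,
        kinds: tuple[str, ...] = KINDS,
        keep_surface: bool = False,
        stride: int = 1,
    ) -> IndexSearchResults:
        entries = {
            kind: exhaustive_search(
                self.spectra, self.trait, kind, keep_surface=keep_surface, stride=stride
            )
            for kind in kinds
        }
        return IndexSearchResults(entries, spectra=self.spectra, trait_name=self.trait_name)
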