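"""Q+K mixed-linear-model genome scan with Bonferroni thresholds and loci.

The association model for one marker is

    y = X a + Q b + u + e,     u ~ N(0, sg^2 K),  e ~ N(0, se^2 I)

with trait y, marker dosage X, structure covariates Q, and a polygenic
random effect whose covariance is the kinship matrix K.  Variance
components are estimated once on the null model (no marker) by REML over
the ratio delta = se^2/sg^2 in the eigenbasis of K, and kept fixed for
every marker test (the P3D/EMMAX strategy; ``mode="exact"`` re-estimates
per marker).  Each marker is then tested by generalized least squares with
a Wald test on the marker effect (Gaussian reference by default, a t
reference optionally for small panels).

Genome-wide thresholds follow the Bonferroni rule P = alpha/n with
alpha = 0.01 (significant) and 0.1 (suggestive), n defaulting to the
number of markers tested.  Loci around each significant lead marker are
delimited by local LD (r^2 >= 0.6 by default) within a window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import GenotypeMatrix

__all__ = [
    "MlmFit",
    "ThresholdSpec",
    "GwasResults",
    "MixedLMGwas",
    "fit_null_mlm",
    "scan",
    "thresholds",
    "locus_intervals",
    "qq_diagnostics",
]

_LOG_DELTA_BRACKET = (-10.0, 10.0)
_DELTA_TOL = 1e-6
_PSD_CLIP_TOL = 1e-6


@dataclass
class MlmFit:
    """Null-model REML fit: variance components and the rotated data.

    ``delta_identifiable`` is False when the REML profile over delta is
    flat (e.g. K proportional to the identity), in which case the scan
    still behaves sensibly — GLS reduces to OLS — but the split of the
    total variance into sg^2/se^2 is arbitrary.
    """

    sigma_g2: float
    sigma_e2: float
    delta: float
    h2: float
    reml_ll: float
    delta_identifiable: bool
    eigvals: np.ndarray          # of the (rescaled) kinship matrix
    rotation: np.ndarray         # U' with K = U diag(eigvals) U'
    y_rot: np.ndarray
    X0_rot: np.ndarray           # intercept + Q, rotated
    n: int = 0
    p: int = 0


@dataclass
class ThresholdSpec:
    """Bonferroni threshold: P = alpha / n independent markers."""

    alpha: float
    n: int
    p_threshold: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        self.p_threshold = self.alpha / self.n


def thresholds(n_markers: int, effective_n: int | None = None) -> tuple[ThresholdSpec, ThresholdSpec]:
    """(significant, suggestive) Bonferroni specs: 0.01/n and 0.1/n."""
    n = effective_n if effective_n else n_markers
    return ThresholdSpec(0.01, n), ThresholdSpec(0.1, n)


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _prepare_K(K, samples=None) -> np.ndarray:
    Km = K.to_numpy(dtype=float) if isinstance(K, pd.DataFrame) else np.asarray(K, float)
    if Km.shape[0] != Km.shape[1]:
        raise ValueError("K must be square")
    if not np.allclose(Km, Km.T, atol=1e-8):
        raise ValueError("K must be symmetric")
    return Km


def _reml_neg_ll(log_delta: float, lam: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    delta = np.exp(log_delta)
    w = 1.0 / (lam + delta)
    n, p = X.shape
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    XtWy = Xw.T @ y
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf
    r = y - X @ beta
    rss = float(np.sum(w * r * r))
    if rss <= 0:
        return np.inf
    sg2 = rss / (n - p)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    sign0, logdet_XtX = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi * sg2)
        + (n - p)
        + np.sum(np.log(lam + delta))
        + logdet_XtWX
        - logdet_XtX
    )
    return -ll


def fit_null_mlm(y, Q, K, samples=None) -> MlmFit:
    """REML fit of the no-marker mixed model by 1-D search over delta.

    K is rescaled to mean diagonal 1 and eigenvalue-clipped at zero for a
    stable search over log delta in [-10, 10] (grid scan plus bounded
    Brent polish, tolerance 1e-6).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if not np.all(np.isfinite(y)):
        raise ValueError("trait values must be finite")
    Km = _prepare_K(K)
    if Km.shape[0] != n:
        raise ValueError("K dimension does not match trait length")
    scale = np.mean(np.diag(Km))
    if scale <= 0:
        raise ValueError("K has non-positive mean diagonal")
    Km = Km / scale
    lam, U = np.linalg.eigh(Km)
    if lam.min() < -_PSD_CLIP_TOL * max(1.0, lam.max()):
        raise ValueError("K is not PSD within clipping tolerance")
    lam = np.clip(lam, 0.0, None)

    X0 = _design(Q, n)
    p = X0.shape[1]
    yr = U.T @ y
    X0r = U.T @ X0

    grid = np.linspace(*_LOG_DELTA_BRACKET, 81)
    vals = np.array([_reml_neg_ll(g, lam, yr, X0r) for g in grid])
    if not np.any(np.isfinite(vals)):
        raise RuntimeError(
            f"REML failed on the whole bracket log delta in {_LOG_DELTA_BRACKET}"
        )
    k = int(np.nanargmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_ll,
        bounds=(lo, hi),
        args=(lam, yr, X0r),
        method="bounded",
        options={"xatol": _DELTA_TOL},
    )
    if not res.success:
        raise RuntimeError(
            f"REML did not converge on bracket [{lo:.3f}, {hi:.3f}]: {res.message}"
        )
    # flat-profile detection: K ~ identity makes every delta equivalent
    finite = vals[np.isfinite(vals)]
    identifiable = bool(finite.max() - finite.min() > 1e-6 * max(1.0, abs(finite.min())))
    delta = float(np.exp(res.x))
    w = 1.0 / (lam + delta)
    Xw = X0r * w[:, None]
    beta = np.linalg.solve(X0r.T @ Xw, Xw.T @ yr)
    r = yr - X0r @ beta
    sg2 = float(np.sum(w * r * r)) / (n - p)
    se2 = sg2 * delta
    return MlmFit(
        sigma_g2=sg2,
        sigma_e2=se2,
        delta=delta,
        h2=sg2 / (sg2 + se2),
        reml_ll=-float(res.fun),
        delta_identifiable=identifiable,
        eigvals=lam,
        rotation=U.T,
        y_rot=yr,
        X0_rot=X0r,
        n=n,
        p=p,
    )


def _design(Q, n: int) -> np.ndarray:
    ones = np.ones((n, 1))
    if Q is None:
        return ones
    Qm = Q.to_numpy(dtype=float) if isinstance(Q, pd.DataFrame) else np.asarray(Q, float)
    if Qm.ndim == 1:
        Qm = Qm[:, None]
    if Qm.shape[0] != n:
        raise ValueError("Q row count does not match trait length")
    X = np.hstack([ones, Qm])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("intercept + Q is rank deficient")
    return X


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

@dataclass
class GwasResults:
    """Per-marker association results plus thresholds and loci."""

    table: pd.DataFrame
    fit: MlmFit
    threshold_n: int
    significant_threshold: float
    suggestive_threshold: float
    mode: str = "p3d"
    loci: pd.DataFrame | None = None

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table.p <= self.significant_threshold]

    @property
    def suggestive(self) -> pd.DataFrame:
        return self.table[self.table.p <= self.suggestive_threshold]

    def qq(self) -> tuple[pd.DataFrame, float]:
        return qq_diagnostics(self.table.p.to_numpy())

    def summary(self) -> str:
        qq_table, lam = self.qq()
        lines = [
            "Mixed-linear-model genome scan",
            "=" * 46,
            f"markers tested      {len(self.table)}",
            f"samples             {self.fit.n}",
            f"mode                {self.mode.upper()}",
            f"sigma_g^2           {self.fit.sigma_g2:.4g}",
            f"sigma_e^2           {self.fit.sigma_e2:.4g}",
            f"pseudo-heritability {self.fit.h2:.3f}"
            + ("" if self.fit.delta_identifiable else "  (delta not identifiable)"),
            f"inflation lambda    {lam:.3f}",
            f"significant P       {self.significant_threshold:.3g} (0.01/{self.threshold_n})",
            f"suggestive P        {self.suggestive_threshold:.3g} (0.1/{self.threshold_n})",
            f"significant markers {len(self.significant)}",
        ]
        if self.loci is not None and len(self.loci):
            lines.append(f"loci                {len(self.loci)}")
            for _, row in self.loci.iterrows():
                lines.append(
                    f"  {row.chrom}:{int(row.start)}-{int(row.end)} "
                    f"lead {row.chrom}:{int(row.lead_pos)} p={row.lead_p:.3g}"
                )
        return "\n".join(lines)

    def plot_manhattan(self, ax=None):
        """Manhattan plot; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0.0
        ticks, labels = [], []
        for i, (chrom, grp) in enumerate(self.table.groupby("chrom", sort=False)):
            x = grp.pos + offset
            ax.scatter(x, grp.neglog10p, s=4, color=f"C{i % 2}")
            ticks.append(float(x.mean()))
            labels.append(str(chrom))
            offset += grp.pos.max() + 1
        for thr, color in (
            (self.significant_threshold, "tab:blue"),
            (self.suggestive_threshold, "tab:red"),
        ):
            ax.axhline(-np.log10(thr), ls="--", lw=0.8, color=color)
        ax.set_xticks(ticks, labels)
        ax.set_xlabel("chromosome")
        ax.set_ylabel(r"$-\log_{10} p$")
        return ax

    def plot_qq(self, ax=None):
        """QQ plot of observed vs expected -log10 p; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(3.2, 3.2))
        table, lam = self.qq()
        ax.scatter(table.expected, table.observed, s=5)
        lim = float(max(table.expected.max(), table.observed.max()))
        ax.plot([0, lim], [0, lim], color="gray", lw=0.8)
        ax.set_xlabel(r"expected $-\log_{10} p$")
        ax.set_ylabel(r"observed $-\log_{10} p$")
        ax.set_title(f"lambda = {lam:.2f}")
        return ax


def scan(
    genotypes: GenotypeMatrix,
    y,
    Q,
    fit: MlmFit,
    variants: pd.DataFrame | None = None,
    mode: str = "p3d",
    effective_n: int | None = None,
    use_t: bool = False,
) -> GwasResults:
    """Per-marker GLS scan under the fitted covariance V = sg^2(K + delta I).

    ``mode="p3d"`` keeps delta fixed from the null fit for every marker;
    ``mode="exact"`` re-estimates it per marker.  Missing genotypes are
    mean-imputed per marker; markers collinear with the covariates get a
    missing p-value.  ``use_t`` selects the small-sample t reference
    (df = n - p) for the Wald statistic; ``False`` uses the Gaussian.
    """
    if mode not in {"p3d", "exact"}:
        raise ValueError("mode must be 'p3d' or 'exact'")
    X = genotypes.imputed()
    n, m = X.shape
    if n != fit.n:
        raise ValueError("genotype sample count does not match the null fit")
    Xr = fit.rotation @ X

    if mode == "p3d":
        eff, se, stat, pval, dfree = _gls_scan(
            fit.y_rot, fit.X0_rot, Xr, fit.eigvals, fit.delta, use_t
        )
    else:
        eff = np.empty(m)
        se = np.empty(m)
        stat = np.empty(m)
        pval = np.empty(m)
        dfree = n - fit.p - 1
        for j in range(m):
            Xj = np.column_stack([fit.X0_rot, Xr[:, j]])
            grid = np.linspace(*_LOG_DELTA_BRACKET, 41)
            vals = [_reml_neg_ll(g, fit.eigvals, fit.y_rot, Xj) for g in grid]
            k = int(np.nanargmin(vals))
            res = optimize.minimize_scalar(
                _reml_neg_ll,
                bounds=(grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]),
                args=(fit.eigvals, fit.y_rot, Xj),
                method="bounded",
                options={"xatol": _DELTA_TOL},
            )
            e, s, t_, p_, _ = _gls_scan(
                fit.y_rot,
                fit.X0_rot,
                Xr[:, j : j + 1],
                fit.eigvals,
                float(np.exp(res.x)),
                use_t,
            )
            eff[j], se[j], stat[j], pval[j] = e[0], s[0], t_[0], p_[0]

    if variants is not None:
        if len(variants) != m:
            raise ValueError("variant table length does not match marker count")
        chrom = variants.chrom.to_numpy()
        pos = variants.pos.to_numpy()
    else:
        chrom = np.repeat("0", m)
        pos = np.arange(1, m + 1)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(pval)
    table = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "effect": eff,
            "se": se,
            "stat": stat,
            "p": pval,
            "neglog10p": neglog,
        }
    )
    sig, sug = thresholds(m, effective_n)
    return GwasResults(
        table=table,
        fit=fit,
        threshold_n=sig.n,
        significant_threshold=sig.p_threshold,
        suggestive_threshold=sug.p_threshold,
        mode=mode,
    )


def _gls_scan(yr, X0r, Xr, lam, delta, use_t):
    """Vectorized per-marker GLS via weighted Frisch-Waugh projection."""
    n, p = X0r.shape
    w = 1.0 / (lam + delta)
    sw = np.sqrt(w)
    A = X0r * sw[:, None]
    qy = yr * sw
    qx = Xr * sw[:, None]
    Q0, _ = np.linalg.qr(A)
    ry = qy - Q0 @ (Q0.T @ qy)
    rx = qx - Q0 @ (Q0.T @ qx)
    xx = np.einsum("ij,ij->j", rx, rx)
    xy = ry @ rx
    dfree = n - p - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(xx > 1e-10, xy / xx, np.nan)
        rss = float(ry @ ry) - eff * xy
        sigma2 = rss / dfree
        se = np.sqrt(sigma2 / xx)
        stat = eff / se
    if use_t:
        pval = 2.0 * stats.t.sf(np.abs(stat), dfree)
    else:
        pval = 2.0 * stats.norm.sf(np.abs(stat))
    pval = np.where(np.isfinite(stat), pval, np.nan)
    return eff, se, stat, pval, dfree


# ---------------------------------------------------------------------------
# loci + diagnostics
# ---------------------------------------------------------------------------

def locus_intervals(
    result: GwasResults,
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    r2_min: float = 0.6,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """LD-delimited locus intervals around significant lead markers.

    Significant markers are visited in order of increasing p; each not yet
    absorbed into an earlier locus becomes a lead, and its interval is the
    minimal span covering every marker within the window whose r^2 with
    the lead is >= ``r2_min``.  Overlapping intervals on one chromosome
    are merged (keeping the better lead).  The result is stored on the
    ``GwasResults`` and returned (chrom, start, end 1-based inclusive).
    """
    sig = result.table[result.table.p <= result.significant_threshold]
    if sig.empty:
        result.loci = pd.DataFrame(columns=["chrom", "start", "end", "lead_pos", "lead_p"])
        return result.loci
    x = genotypes.imputed()
    xc = x - x.mean(axis=0)
    sd = x.std(axis=0)
    pos = variants.pos.to_numpy()
    chroms = variants.chrom.to_numpy()

    intervals = []
    claimed = set()
    for idx in sig.sort_values("p").index:
        if idx in claimed:
            continue
        lead_chrom, lead_pos = chroms[idx], pos[idx]
        in_window = np.flatnonzero(
            (chroms == lead_chrom) & (np.abs(pos - lead_pos) <= window_bp)
        )
        if sd[idx] == 0:
            linked = np.array([idx])
        else:
            ok = in_window[sd[in_window] > 0]
            r = (xc[:, idx] @ xc[:, ok]) / (x.shape[0] * sd[idx] * sd[ok])
            linked = ok[r * r >= r2_min]
            if linked.size == 0:
                linked = np.array([idx])
        for j in linked:
            claimed.add(int(j))
        intervals.append(
            {
                "chrom": lead_chrom,
                "start": int(pos[linked].min()),
                "end": int(pos[linked].max()),
                "lead_pos": int(lead_pos),
                "lead_p": float(result.table.p.iloc[idx]),
            }
        )
    merged: list[dict] = []
    for iv in sorted(intervals, key=lambda d: (str(d["chrom"]), d["start"])):
        if merged and merged[-1]["chrom"] == iv["chrom"] and iv["start"] <= merged[-1]["end"]:
            merged[-1]["end"] = max(merged[-1]["end"], iv["end"])
            if iv["lead_p"] < merged[-1]["lead_p"]:
                merged[-1]["lead_pos"], merged[-1]["lead_p"] = iv["lead_pos"], iv["lead_p"]
        else:
            merged.append(dict(iv))
    result.loci = pd.DataFrame(merged, columns=["chrom", "start", "end", "lead_pos", "lead_p"])
    return result.loci


def qq_diagnostics(pvalues) -> tuple[pd.DataFrame, float]:
    """Observed-vs-expected -log10 p table and the genomic inflation factor.

    lambda = median of the chi-square(1) statistics implied by the
    p-values, divided by the null median 0.4549.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 10:
        raise ValueError("need >= 10 p-values for QQ diagnostics")
    obs = np.sort(p)
    expected = (np.arange(1, p.size + 1) - 0.5) / p.size
    table = pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(obs)}
    )
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
    return table, lam


# ---------------------------------------------------------------------------
# model facade
# ---------------------------------------------------------------------------

class MixedLMGwas:
    """Q+K mixed-model GWAS posed as a fittable model.

    Parameters
    ----------
    y:
        Trait vector (array or Series aligned to ``genotypes.samples``).
    genotypes:
        MAF-filtered :class:`~spec2gwas.io_formats.GenotypeMatrix`.
    K:
        Kinship matrix (DataFrame or array, samples in genotype order).
    Q:
        Optional structure covariates (PCs or ancestry fractions).
    variants:
        Optional variant table supplying (chrom, pos) per marker.
    """

    def __init__(self, y, genotypes: GenotypeMatrix, K, Q=None, variants=None):
        if isinstance(y, pd.Series):
            y = y.reindex(genotypes.samples).to_numpy(dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.genotypes = genotypes
        self.K = K
        self.Q = Q
        self.variants = variants

    def fit(
        self,
        mode: str = "p3d",
        effective_n: int | None = None,
        use_t: bool = False,
        r2_min: float = 0.6,
        call_loci: bool = True,
        loco: bool = False,
    ) -> GwasResults:
        """Run the scan.  ``loco=True`` rebuilds K and the null fit per
        chromosome from all *other* chromosomes (leave-one-chromosome-out),
        which removes the tested markers' own contribution to the random
        effect; it requires a variant table and marker-derived kinship is
        recomputed internally, ignoring the supplied K."""
        if not loco:
            null = fit_null_mlm(self.y, self.Q, self.K)
            result = scan(
                self.genotypes,
                self.y,
                self.Q,
                null,
                variants=self.variants,
                mode=mode,
                effective_n=effective_n,
                use_t=use_t,
            )
        else:
            result = self._fit_loco(mode, effective_n, use_t)
        if call_loci and self.variants is not None:
            locus_intervals(result, self.genotypes, self.variants, r2_min=r2_min)
        return result

    def _fit_loco(self, mode, effective_n, use_t) -> GwasResults:
        from .popgen import kinship as _kinship

        if self.variants is None:
            raise ValueError("LOCO needs a variant table to define chromosomes")
        m = self.genotypes.n_markers
        chroms = self.variants.chrom.to_numpy()
        pieces = []
        null = None
        for chrom in pd.unique(chroms):
            on = chroms == chrom
            if on.all():
                raise ValueError("LOCO needs at least two chromosomes")
            K_off = _kinship(self.genotypes.take_markers(~on))
            fit_c = fit_null_mlm(self.y, self.Q, K_off)
            res_c = scan(
                self.genotypes.take_markers(on),
                self.y,
                self.Q,
                fit_c,
                variants=self.variants[on].reset_index(drop=True),
                mode=mode,
                use_t=use_t,
            )
            tab = res_c.table.copy()
            tab.index = np.flatnonzero(on)
            pieces.append(tab)
            if null is None:
                null = fit_c
        table = pd.concat(pieces).sort_index().reset_index(drop=True)
        sig, sug = thresholds(m, effective_n)
        return GwasResults(
            table=table,
            fit=null,
            threshold_n=sig.n,
            significant_threshold=sig.p_threshold,
            suggestive_threshold=sug.p_threshold,
            mode=f"{mode}-loco",
        )
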