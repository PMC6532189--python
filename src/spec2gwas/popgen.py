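"""Variant filtration and population-structure quantities.

Implements the positional SNP/indel filters, the MAF >= 0.05 marker
screen, a VanRaden-style genomic kinship matrix, PCA structure covariates,
windowed LD decay with an LD50 summary, and a neighbor-joining tree on
p-distances with marker bootstrap supports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from .io_formats import GenotypeMatrix

__all__ = [
    "apply_variant_filters",
    "maf_filter",
    "minor_allele_frequency",
    "kinship",
    "pca_covariates",
    "LDProfile",
    "ld_profile",
    "p_distance_matrix",
    "nj_tree",
]


# ---------------------------------------------------------------------------
# positional variant filters
# ---------------------------------------------------------------------------

def apply_variant_filters(
    variants: pd.DataFrame,
    snp_cluster_bp: int = 5,
    snp_near_indel_bp: int = 5,
    indel_adjacent_bp: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strict positional filtration of a sorted variant table.

    Three rules, all evaluated on the original set simultaneously, with the
    union of removals applied:

    1. SNP clusters — two SNPs at distance <= ``snp_cluster_bp`` on one
       chromosome: *both* removed.
    2. SNPs near indels — a SNP within <= ``snp_near_indel_bp`` of any
       indel: the SNP removed (the indel stays).
    3. Adjacent indels — two indels at distance strictly <
       ``indel_adjacent_bp``: both removed.

    Returns ``(kept, removed)`` where ``removed`` carries a ``rule``
    column.  Input must be sorted by (chrom, pos).
    """
    v = variants.reset_index(drop=True)
    if v.empty:
        removed = v.copy()
        removed["rule"] = pd.Series(dtype=str)
        return v.copy(), removed
    for chrom, grp in v.groupby("chrom", sort=False):
        if not grp.pos.is_monotonic_increasing:
            raise ValueError(
                f"variant table must be position-sorted within chromosomes ({chrom})"
            )
    rules = {i: [] for i in range(len(v))}
    for _, grp in v.groupby("chrom", sort=False):
        snps = grp[grp.vtype == "SNP"]
        indels = grp[grp.vtype == "indel"]
        spos = snps.pos.to_numpy()
        ipos = indels.pos.to_numpy()
        sidx = snps.index.to_numpy()
        iidx = indels.index.to_numpy()
        # rule 1: SNP pairs at distance <= snp_cluster_bp (both removed)
        if len(spos) > 1:
            d = np.diff(spos)
            hit = d <= snp_cluster_bp
            for k in np.flatnonzero(hit):
                rules[sidx[k]].append("snp-cluster")
                rules[sidx[k + 1]].append("snp-cluster")
        # rule 2: SNP within <= snp_near_indel_bp of any indel (SNP removed)
        if len(spos) and len(ipos):
            j = np.searchsorted(ipos, spos)
            left = np.where(j > 0, spos - ipos[np.maximum(j - 1, 0)], np.inf)
            right = np.where(
                j < len(ipos), ipos[np.minimum(j, len(ipos) - 1)] - spos, np.inf
            )
            hit = np.minimum(left, right) <= snp_near_indel_bp
            for k in np.flatnonzero(hit):
                rules[sidx[k]].append("near-indel")
        # rule 3: indel pairs at distance < indel_adjacent_bp (both removed)
        if len(ipos) > 1:
            d = np.diff(ipos)
            hit = d < indel_adjacent_bp
            for k in np.flatnonzero(hit):
                rules[iidx[k]].append("adjacent-indel")
                rules[iidx[k + 1]].append("adjacent-indel")
    removed_mask = np.array([bool(rules[i]) for i in range(len(v))])
    removed = v[removed_mask].copy()
    removed["rule"] = [",".join(sorted(set(rules[i]))) for i in np.flatnonzero(removed_mask)]
    return v[~removed_mask].copy(), removed


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------

def minor_allele_frequency(dosages: np.ndarray) -> np.ndarray:
    """Per-marker MAF from a dosage matrix, computed on non-missing calls.

    All-missing markers get NaN.
    """
    counts = np.sum(~np.isnan(dosages), axis=0)
    sums = np.nansum(dosages, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(counts > 0, sums / (2.0 * counts), np.nan)
    return np.minimum(p, 1.0 - p)


def maf_filter(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame | None = None,
    threshold: float = 0.05,
) -> tuple[GenotypeMatrix, pd.DataFrame | None, np.ndarray]:
    """Keep markers with MAF >= threshold (inclusive); drop all-missing markers.

    Returns ``(genotypes, variants, keep_mask)`` with the variant table
    subset in step when provided.
    """
    maf = minor_allele_frequency(genotypes.dosages)
    keep = np.isfinite(maf) & (maf >= threshold)
    kept_variants = variants[keep].reset_index(drop=True) if variants is not None else None
    return genotypes.take_markers(keep), kept_variants, keep


# ---------------------------------------------------------------------------
# kinship + PCA
# ---------------------------------------------------------------------------

def kinship(genotypes: GenotypeMatrix, estimator: str = "vanraden") -> pd.DataFrame:
    """Genomic relationship matrix from standardized dosages.

    VanRaden-style centered cross-product: per marker, dosages are centered
    at 2p and scaled by sqrt(2p(1-p)); K = Z Z' / m over the m markers with
    nonzero variance.  Missing calls are mean-imputed first.  The estimator
    tag is stored in ``DataFrame.attrs["estimator"]``.
    """
    if estimator != "vanraden":
        raise ValueError(f"unknown kinship estimator {estimator!r}")
    x = genotypes.imputed()
    p = x.mean(axis=0) / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    ok = denom > 0
    z = (x[:, ok] - 2.0 * p[ok]) / denom[ok]
    m = int(ok.sum())
    if m == 0:
        raise ValueError("no polymorphic markers for kinship")
    K = z @ z.T / m
    out = pd.DataFrame(K, index=genotypes.samples, columns=genotypes.samples)
    out.attrs["estimator"] = "vanraden"
    return out


def pca_covariates(genotypes: GenotypeMatrix, q: int) -> pd.DataFrame:
    """Top-q principal-component scores of standardized genotypes.

    Sign convention: within each component the loading of largest absolute
    value is made positive, so results are reproducible across runs and
    permutation-equivariant in sample order.
    """
    n = genotypes.n_samples
    if q >= n:
        raise ValueError("q must be smaller than the sample count")
    x = genotypes.imputed()
    p = x.mean(axis=0) / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    ok = denom > 0
    z = (x[:, ok] - 2.0 * p[ok]) / denom[ok]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :q] * s[:q]
    for j in range(q):
        k = int(np.argmax(np.abs(vt[j])))
        if vt[j, k] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(
        scores, index=genotypes.samples, columns=[f"PC{j + 1}" for j in range(q)]
    )


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

@dataclass
class LDProfile:
    """Pairwise r^2 records within a window plus the binned decay curve."""

    pairs: pd.DataFrame          # columns: chrom, distance_bp, r2
    curve: pd.DataFrame          # columns: bin_center_bp, mean_r2, n_pairs
    ld50_bp: float | None        # None when the curve never falls to half max


def _running_median(x: np.ndarray, k: int = 5) -> np.ndarray:
    half = k // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        out[i] = np.median(x[max(0, i - half) : i + half + 1])
    return out


def ld_profile(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    window_bp: int = 1_000_000,
    bin_bp: int = 5_000,
) -> LDProfile:
    """LD decay: r^2 of dosage vectors for same-chromosome pairs in a window.

    The decay curve is the mean r^2 per distance bin (default 5 kb).  LD50
    is the smallest bin center at which the running-median-smoothed curve
    falls to half the curve's global maximum.
    """
    x = genotypes.imputed()
    records = []
    for chrom, grp in variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp.pos.to_numpy()
        if len(idx) < 2:
            continue
        if not np.all(np.diff(pos) >= 0):
            raise ValueError("markers must be position-sorted within chromosomes")
        sub = x[:, idx]
        sd = sub.std(axis=0)
        c = sub - sub.mean(axis=0)
        for i in range(len(idx) - 1):
            jmax = int(np.searchsorted(pos, pos[i] + window_bp, side="right"))
            if jmax <= i + 1:
                continue
            if sd[i] == 0:
                continue
            js = np.arange(i + 1, jmax)
            ok = sd[js] > 0
            js = js[ok]
            if js.size == 0:
                continue
            r = (c[:, i] @ c[:, js]) / (len(sub) * sd[i] * sd[js])
            records.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "distance_bp": pos[js] - pos[i],
                        "r2": np.clip(r * r, 0.0, 1.0),
                    }
                )
            )
    if not records:
        raise ValueError("no same-chromosome marker pairs within the window")
    pairs = pd.concat(records, ignore_index=True)
    bins = (pairs.distance_bp // bin_bp).astype(int)
    curve = (
        pairs.assign(bin=bins)
        .groupby("bin")
        .agg(mean_r2=("r2", "mean"), n_pairs=("r2", "size"))
        .reset_index()
    )
    curve["bin_center_bp"] = (curve.pop("bin") + 0.5) * bin_bp
    curve = curve[["bin_center_bp", "mean_r2", "n_pairs"]]
    smoothed = _running_median(curve.mean_r2.to_numpy())
    half = smoothed.max() / 2.0
    below = np.flatnonzero(smoothed <= half)
    ld50 = float(curve.bin_center_bp.iloc[below[0]]) if below.size else None
    return LDProfile(pairs=pairs, curve=curve, ld50_bp=ld50)


# ---------------------------------------------------------------------------
# neighbor-joining tree on p-distances
# ---------------------------------------------------------------------------

def p_distance_matrix(genotypes: GenotypeMatrix) -> skbio.DistanceMatrix:
    """Pairwise p-distance: fraction of mutually non-missing markers whose
    dosage calls differ."""
    x = genotypes.dosages
    n = x.shape[0]
    d = np.zeros((n, n))
    finite = np.isfinite(x)
    for i in range(n):
        for j in range(i + 1, n):
            both = finite[i] & finite[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"samples {genotypes.samples[i]} and {genotypes.samples[j]} "
                    "share no called markers"
                )
            d[i, j] = d[j, i] = float(np.mean(x[i, both] != x[j, both]))
    return skbio.DistanceMatrix(d, ids=[str(s) for s in genotypes.samples])


def nj_tree(
    genotypes: GenotypeMatrix,
    bootstrap_reps: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[skbio.TreeNode, dict[frozenset, float] | None]:
    """Neighbor-joining tree on dosage p-distances, with optional bootstrap.

    Bootstrap resamples marker columns with replacement; support for each
    internal bipartition of the point-estimate tree is the fraction of
    replicate trees containing it.  Returns ``(tree, supports)`` where
    supports maps tip-name frozensets to support fractions (None when
    ``bootstrap_reps == 0``).
    """
    if genotypes.n_samples < 3:
        raise ValueError("need >= 3 samples for a tree")
    tree = skbio.tree.nj(p_distance_matrix(genotypes))
    if bootstrap_reps <= 0:
        return tree, None
    rng = rng or np.random.default_rng()
    target = _bipartitions(tree)
    counts = {bp: 0 for bp in target}
    m = genotypes.n_markers
    for _ in range(bootstrap_reps):
        cols = rng.integers(0, m, size=m)
        boot = GenotypeMatrix(genotypes.dosages[:, cols], list(genotypes.samples))
        boot_tree = skbio.tree.nj(p_distance_matrix(boot))
        found = _bipartitions(boot_tree)
        for bp in counts:
            if bp in found:
                counts[bp] += 1
    supports = {bp: counts[bp] / bootstrap_reps for bp in counts}
    return tree, supports


def _bipartitions(tree: skbio.TreeNode) -> set[frozenset]:
    """Unrooted bipartitions (as the smaller-or-canonical tip set) of internal edges."""
    all_tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            other = all_tips - side
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out
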