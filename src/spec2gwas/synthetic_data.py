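"""Synthetic genotypes, traits, variants and raw spectral frames with truth.

Every pipeline stage can be exercised without external data: a
Balding-Nichols population simulator provides structured biallelic
genotypes on 12 chromosomes; an additive trait simulator plants causal
markers at a chosen narrow-sense heritability and rescales the trait to
the target moments (mean 8.62, SD 0.77 by default, emulating a seed crude
protein content in percent); a spectral simulator emits raw instrument
frames (three replicates plus white/dark references) whose absorption
depth near the planted wavelength pair is affine in the trait; and a
variant-table generator plants known positional-filter violations.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix
from .spectra_preprocess import SpectraSet

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticFrames",
    "simulate_population",
    "simulate_trait",
    "simulate_spectra",
    "simulate_variants_for_filtering",
    "simulate_ld_population",
    "write_vcf",
]

_CHROMS = [str(i) for i in range(1, 13)]
_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic panel.

    Defaults emulate the study design this package targets: 80 accessions
    in ~6 subpopulations, a protein-like trait ~ Normal(8.62, 0.77^2) in
    percent, reflectance on a 350-2500 nm grid with the informative
    absorption pair at (1227, 1177) nm.
    """

    n_samples: int = 80
    n_snps: int = 2000
    k_subpops: int = 6
    fst: float = 0.2
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_causal: int = 2
    h2: float = 0.7
    trait_mean: float = 8.62
    trait_sd: float = 0.77
    planted_pair: tuple[float, float] = (1227.0, 1177.0)
    spectral_noise_sd: float = 0.0015
    grid_low: float = 350.0
    grid_high: float = 2500.0
    grid_step: float = 1.0
    snp_spacing_bp: int = 10_000
    replicates: int = 3
    require_normal_trait: bool = True
    seed: int = 0

    # spectral-shape constants (see docs/methods.md for the design study);
    # the two baseline deviation scales balance so that the planted pair is
    # the true NDSI optimum: the short scale penalizes near-pairs inside
    # the absorption flanks, the long scale penalizes distant references
    absorption_sigma_nm: float = 18.0
    absorption_depth: float = 0.07
    absorption_slope: float = 0.02      # depth change per trait SD
    baseline_scale_sd: float = 0.005    # per-sample multiplicative deviation
    baseline_tilt_sd: float = 0.05      # per-sample tilt over the full range
    baseline_rough_sd: float = 0.002    # short-scale per-sample deviation
    baseline_rough_length_nm: float = 14.0
    baseline_smooth_sd: float = 0.0021  # mid-scale per-sample deviation
    baseline_smooth_length_nm: float = 45.0

    def __post_init__(self) -> None:
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must lie in [0, 1]")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("MAF bounds must satisfy 0 < low <= high <= 0.5")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must lie in [0, 1)")
        lo, hi = self.grid_low, self.grid_high
        for lam in self.planted_pair:
            if not lo <= lam <= hi:
                raise ValueError(f"planted wavelength {lam} outside the grid")

    def grid(self) -> np.ndarray:
        return np.arange(self.grid_low, self.grid_high + self.grid_step / 2, self.grid_step)


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators for test oracles."""

    causal_indices: np.ndarray
    causal_effects: np.ndarray
    subpop_labels: np.ndarray
    planted_pair: tuple[float, float]
    genetic_values: np.ndarray      # on the final trait scale
    trait: np.ndarray
    var_genetic: float
    var_residual: float


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_population(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, np.ndarray]:
    """Balding-Nichols structured genotypes on 12 chromosomes.

    Ancestral frequencies are Uniform(maf_low, maf_high); each subpopulation
    draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) and genotypes are
    Binomial(2, p_subpop).  ``fst == 0`` yields panmixia (a degenerate but
    valid limit).  Positions are uniformly spaced; returns
    (genotypes, variant table, subpop labels).
    """
    rng = np.random.default_rng(cfg.seed)
    n, m, k = cfg.n_samples, cfg.n_snps, cfg.k_subpops
    labels = np.arange(n) % k
    p_anc = rng.uniform(cfg.maf_low, cfg.maf_high, size=m)
    if cfg.fst > 0 and k > 1:
        a = p_anc * (1 - cfg.fst) / cfg.fst
        b = (1 - p_anc) * (1 - cfg.fst) / cfg.fst
        p_sub = rng.beta(a, b, size=(k, m))
    else:
        p_sub = np.tile(p_anc, (k, 1))
    dos = rng.binomial(2, p_sub[labels, :]).astype(float)

    per_chrom = int(np.ceil(m / len(_CHROMS)))
    chroms, pos = [], []
    for j in range(m):
        c, i = divmod(j, per_chrom)
        chroms.append(_CHROMS[c])
        pos.append((i + 1) * cfg.snp_spacing_bp)
    ref = rng.choice(4, size=m)
    alt = (ref + rng.integers(1, 4, size=m)) % 4
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": _BASES[ref],
            "alt": _BASES[alt],
            "vtype": "SNP",
        }
    )
    samples = [f"S{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(dos, samples), variants, labels


# ---------------------------------------------------------------------------
# trait
# ---------------------------------------------------------------------------

def simulate_trait(
    genotypes: GenotypeMatrix,
    cfg: SimulationConfig,
    subpop_labels: np.ndarray | None = None,
) -> tuple[pd.Series, SyntheticTruth]:
    """Additive trait y = sum g_i b_i + e at heritability h2.

    Causal markers are drawn among reasonably common ones (realized
    MAF >= 0.2 where available) so the planted signal is detectable at the
    configured sample size; effects are Normal draws rescaled so
    Var(genetic)/Var(total) = h2 on the realized genotypes.  The final
    vector is affinely rescaled to (trait_mean, trait_sd), which preserves
    h2 exactly.
    """
    from scipy import stats as _stats

    rng = np.random.default_rng(cfg.seed + 1)
    x = genotypes.imputed()
    n, m = x.shape
    maf = np.minimum(x.mean(axis=0) / 2, 1 - x.mean(axis=0) / 2)
    common = np.flatnonzero(maf >= 0.2)
    pool = common if common.size >= cfg.n_causal else np.arange(m)
    causal = np.sort(rng.choice(pool, size=cfg.n_causal, replace=False))

    # redraw until the trait both has genetic variance and, when requested,
    # passes the downstream normality gate: the emulated study design only
    # admits traits that survive that screen
    for _ in range(50):
        b = rng.normal(size=cfg.n_causal)
        g = x[:, causal] @ b
        if cfg.h2 == 0 or g.std() == 0:
            b = np.zeros(cfg.n_causal)
            g = np.zeros(n)
            e = rng.normal(size=n)
        else:
            # rescale effects so Var(genetic) = h2 on a unit-total-variance scale
            b = b * np.sqrt(cfg.h2) / g.std()
            g = x[:, causal] @ b
            e = rng.normal(scale=np.sqrt(1 - cfg.h2), size=n)
        y = g + e
        if not cfg.require_normal_trait or n < 8 or _stats.shapiro(y).pvalue >= 0.05:
            break
    else:
        raise RuntimeError("could not draw an admissible trait in 50 attempts")
    # affine rescale of the final vector to the target moments
    s = y.std(ddof=1)
    a = cfg.trait_sd / s if s > 0 else 0.0
    c = cfg.trait_mean - a * y.mean()
    y_final = a * y + c
    g_final = a * g  # genetic deviations on the final scale

    samples = [str(s_) for s_ in genotypes.samples]
    truth = SyntheticTruth(
        causal_indices=causal,
        causal_effects=b * a if cfg.h2 > 0 else b,
        subpop_labels=(
            subpop_labels if subpop_labels is not None else np.zeros(n, dtype=int)
        ),
        planted_pair=cfg.planted_pair,
        genetic_values=g_final,
        trait=y_final,
        var_genetic=float(np.var(g_final)),
        var_residual=float(np.var(a * e)),
    )
    return pd.Series(y_final, index=samples, name="PC"), truth


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

@dataclass
class SyntheticFrames:
    """Raw frames as the instrument would deliver them, plus the truth."""

    raw: SpectraSet        # (sample, replicate) x wavelength intensity
    white: SpectraSet
    dark: SpectraSet
    true_reflectance: SpectraSet


def _baseline(wl: np.ndarray) -> np.ndarray:
    """Smooth seed-reflectance-like baseline: wide Gaussians plus the
    trait-independent water-absorption dips near 1450 and 1940 nm."""
    comps = [
        (0.35, 1080.0, 420.0),
        (0.18, 1700.0, 550.0),
        (0.10, 2350.0, 300.0),
        (-0.08, 1450.0, 90.0),
        (-0.12, 1940.0, 110.0),
    ]
    base = 0.25 + sum(a * np.exp(-0.5 * ((wl - mu) / s) ** 2) for a, mu, s in comps)
    return base


def _noise_envelope(wl: np.ndarray, quiet_bands: tuple[float, ...] = ()) -> np.ndarray:
    """Relative amplitude of per-sample deviations and replicate noise.

    Real spectroradiometers are noisiest where little light survives (the
    water-absorption bands) and around the 1000-1100 nm detector junction;
    the envelope raises every noise source there.  ``quiet_bands`` marks
    low-noise instrument windows (the planted working wavelengths), which
    makes the planted pair the unique population-level optimum of the
    index search — the property the recovery tests rely on.
    """
    env = (
        1.0
        + 6.0 * np.exp(-0.5 * ((wl - 1450.0) / 90.0) ** 2)
        + 2.5 * np.exp(-0.5 * ((wl - 1940.0) / 110.0) ** 2)
        + 1.5 * np.exp(-0.5 * ((wl - 1090.0) / 45.0) ** 2)
        + 4.0 * np.exp(-0.5 * ((wl - 420.0) / 60.0) ** 2)
        + 4.0 * np.exp(-0.5 * ((wl - 2430.0) / 80.0) ** 2)
    )
    for center in quiet_bands:
        env = env * (1.0 - 0.65 * np.exp(-0.5 * ((wl - center) / 7.0) ** 2))
    return env


def _white_frame(wl: np.ndarray) -> np.ndarray:
    """Halogen-lamp-shaped white-reference intensity (instrument units)."""
    return 800.0 + 3500.0 * np.exp(-0.5 * ((wl - 1100.0) / 700.0) ** 2)


def _dark_frame(wl: np.ndarray) -> np.ndarray:
    """Small positive banded dark current."""
    return 60.0 + 0.01 * (wl - wl[0])


def _gp_field(
    rng: np.random.Generator,
    wl: np.ndarray,
    n: int,
    sd: float,
    length_nm: float,
) -> np.ndarray:
    """Stationary smooth random field: Gaussian bumps with iid amplitudes.

    Centers every length/2 nm, bump width = length; normalized so the
    pointwise SD equals ``sd``.  The implied correlation decays roughly as
    exp(-dx^2 / (4 length^2)).
    """
    centers = np.arange(wl[0] - 2 * length_nm, wl[-1] + 2 * length_nm, length_nm / 2)
    bumps = np.exp(-0.5 * ((wl[None, :] - centers[:, None]) / length_nm) ** 2)
    amps = rng.normal(scale=sd, size=(n, centers.size))
    norm = np.sqrt(np.mean(np.sum(bumps**2, axis=0)))
    return (amps @ bumps) / norm


def simulate_spectra(
    trait: pd.Series | np.ndarray,
    cfg: SimulationConfig,
) -> SyntheticFrames:
    """Raw spectral frames whose absorption depth at lambda_a is affine in
    the trait.

    True reflectance = smooth baseline x per-sample smooth deviation
    (multiplicative scale, tilt, and a mid-scale bump field) minus an
    absorption Gaussian centered at lambda_a whose depth is
    ``absorption_depth + absorption_slope * (trait - mean)/sd``; lambda_b
    sits on the baseline outside the absorption feature.  Frames are
    constructed so that white/dark calibration recovers the true
    reflectance exactly in the noiseless case:
    I_raw = I_dark + (R_true + noise) * (I_white - I_dark).
    """
    if isinstance(trait, pd.Series):
        samples = [str(s) for s in trait.index]
        t = trait.to_numpy(dtype=float)
    else:
        t = np.asarray(trait, dtype=float)
        samples = [f"S{i + 1:03d}" for i in range(t.size)]
    if not np.all(np.isfinite(t)):
        raise ValueError("trait values must be finite")
    rng = np.random.default_rng(cfg.seed + 2)
    wl = cfg.grid()
    n = t.size
    lam_a, lam_b = cfg.planted_pair

    base = _baseline(wl)
    t_std = (t - cfg.trait_mean) / cfg.trait_sd if cfg.trait_sd > 0 else t * 0

    # per-sample baseline deviations, uncorrelated with the trait
    scale = 1.0 + rng.normal(scale=cfg.baseline_scale_sd, size=n)
    tilt = rng.normal(scale=cfg.baseline_tilt_sd, size=n)
    span = wl[-1] - wl[0]
    envelope = _noise_envelope(wl, quiet_bands=cfg.planted_pair)
    field_dev = envelope[None, :] * (
        _gp_field(rng, wl, n, cfg.baseline_rough_sd, cfg.baseline_rough_length_nm)
        + _gp_field(rng, wl, n, cfg.baseline_smooth_sd, cfg.baseline_smooth_length_nm)
    )

    depth = cfg.absorption_depth + cfg.absorption_slope * t_std
    if np.any(depth < 0):
        raise ValueError("absorption depth went negative; lower absorption_slope")
    absorb = np.exp(-0.5 * ((wl - lam_a) / cfg.absorption_sigma_nm) ** 2)
    refl = (
        base[None, :] * (scale[:, None] + tilt[:, None] * (wl[None, :] - 1400.0) / span)
        + field_dev
        - depth[:, None] * absorb[None, :]
    )
    if np.any(refl <= 0):
        raise ValueError("true reflectance hit zero; generator config unphysical")

    white = _white_frame(wl)
    dark = _dark_frame(wl)
    gain = white - dark

    reps = []
    for r in range(cfg.replicates):
        noise = envelope[None, :] * rng.normal(
            scale=cfg.spectral_noise_sd, size=refl.shape
        )
        reps.append(dark[None, :] + (refl + noise) * gain[None, :])
    raw = np.concatenate(reps, axis=0)
    index = pd.MultiIndex.from_arrays(
        [
            np.tile(samples, cfg.replicates),
            np.repeat(np.arange(1, cfg.replicates + 1), n),
        ],
        names=["sample_id", "replicate"],
    )
    raw_set = SpectraSet(pd.DataFrame(raw, index=index, columns=wl), role="raw")
    white_set = SpectraSet(
        pd.DataFrame(white[None, :], index=pd.Index(["white"]), columns=wl), role="white"
    )
    dark_set = SpectraSet(
        pd.DataFrame(dark[None, :], index=pd.Index(["dark"]), columns=wl), role="dark"
    )
    true_set = SpectraSet(
        pd.DataFrame(refl, index=pd.Index(samples, name="sample_id"), columns=wl),
        role="calibrated",
    )
    return SyntheticFrames(raw_set, white_set, dark_set, true_set)


# ---------------------------------------------------------------------------
# variant-filter fixture
# ---------------------------------------------------------------------------

def simulate_variants_for_filtering(seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Variant table with planted positional-filter violations and truth.

    Plants, on chromosome 1 with generous spacing between cases: SNP
    cluster pairs (distance <= 5 bp, both to be removed), SNPs within 5 bp
    of an indel (SNP removed, indel kept), adjacent indel pairs (distance
    < 10 bp, both removed), and boundary cases that must survive (SNPs 6 bp
    apart, indels exactly 10 bp apart, SNP 6 bp from an indel).  The truth
    dict records the expected removals per rule.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    removed = {"snp-cluster": [], "near-indel": [], "adjacent-indel": []}

    def add(pos, vtype, ref=None, alt=None):
        ref = ref or "A"
        alt = alt or ("T" if vtype == "SNP" else "AT")
        rows.append({"chrom": "1", "pos": int(pos), "ref": ref, "alt": alt, "vtype": vtype})
        return int(pos)

    cursor = 1000
    step = 500  # far beyond every rule distance

    # clean singletons
    for _ in range(6):
        add(cursor, "SNP")
        cursor += step
    for _ in range(3):
        add(cursor, "indel")
        cursor += step
    # planted SNP clusters: two pairs (4 SNPs removed)
    for gap in (3, 5):
        a = add(cursor, "SNP")
        b = add(cursor + gap, "SNP")
        removed["snp-cluster"] += [a, b]
        cursor += step
    # SNPs near indels: two cases (2 SNPs removed, indels kept)
    for gap in (2, 5):
        s = add(cursor, "SNP")
        add(cursor + gap, "indel")
        removed["near-indel"].append(s)
        cursor += step
    # adjacent indels: one pair at 9 bp (both removed)
    a = add(cursor, "indel")
    b = add(cursor + 9, "indel")
    removed["adjacent-indel"] += [a, b]
    cursor += step
    # boundary survivors
    add(cursor, "SNP")
    add(cursor + 6, "SNP")           # 6 bp apart: kept
    cursor += step
    add(cursor, "indel")
    add(cursor + 10, "indel")        # exactly 10 bp: kept (strict <)
    cursor += step
    s = add(cursor, "SNP")
    add(cursor + 6, "indel")         # 6 bp from indel: kept
    cursor += step
    # a little random shuffle-resistant padding
    for _ in range(int(rng.integers(2, 5))):
        add(cursor, "SNP")
        cursor += step

    variants = (
        pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    )
    all_removed = sorted(set(sum(removed.values(), [])))
    truth = {
        "removed_by_rule": removed,
        "removed_positions": all_removed,
        "kept_positions": sorted(set(variants.pos) - set(all_removed)),
    }
    return variants, truth


# ---------------------------------------------------------------------------
# LD-decay population
# ---------------------------------------------------------------------------

def simulate_ld_population(
    n_samples: int = 100,
    n_snps: int = 400,
    spacing_bp: int = 2_000,
    ld50_bp: float = 50_000.0,
    freq: float = 0.5,
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """One-chromosome panel with exponentially decaying LD of known half-distance.

    Haplotypes follow a Markov copying chain: each next allele copies its
    left neighbour with probability c = exp(-ln2 * spacing / (2 * ld50)),
    otherwise redraws Bernoulli(freq).  The dosage r^2 between two markers
    d bp apart is then exp(-ln2 * d / ld50) in expectation, i.e. the r^2
    decay curve halves at ``ld50_bp``.
    """
    rng = np.random.default_rng(seed)
    c = np.exp(-np.log(2.0) * spacing_bp / (2.0 * ld50_bp))
    haps = np.empty((2 * n_samples, n_snps), dtype=np.int8)
    haps[:, 0] = rng.random(2 * n_samples) < freq
    for j in range(1, n_snps):
        copy = rng.random(2 * n_samples) < c
        fresh = rng.random(2 * n_samples) < freq
        haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
    dos = (haps[0::2] + haps[1::2]).astype(float)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": (np.arange(n_snps) + 1) * spacing_bp,
            "ref": "A",
            "alt": "T",
            "vtype": "SNP",
        }
    )
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    return GenotypeMatrix(dos, samples), variants


# ---------------------------------------------------------------------------
# VCF emission
# ---------------------------------------------------------------------------

def write_vcf(
    variants: pd.DataFrame,
    genotypes: GenotypeMatrix | None,
    path,
) -> None:
    """Write variants (and optional genotypes) as an uncompressed VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(variants.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if genotypes is not None:
            cols += ["FORMAT"] + [str(s) for s in genotypes.samples]
        fh.write("\t".join(cols) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, row in enumerate(variants.itertuples(index=False)):
            fields = [
                str(row.chrom),
                str(int(row.pos)),
                ".",
                str(row.ref),
                str(row.alt),
                ".",
                "PASS",
                ".",
            ]
            if genotypes is not None:
                fields.append("GT")
                col = genotypes.dosages[:, j]
                fields += [
                    gt_map.get(v, "./.") if np.isfinite(v) else "./." for v in col
                ]
            fh.write("\t".join(fields) + "\n")
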