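"""End-to-end pipeline: simulate -> preprocess -> index search -> popgen ->
mixed-model GWAS -> trait-vs-trait comparison, from one config and seed.

``run_pipeline`` wires every stage together on synthetic data with planted
truth and returns all intermediate objects, so a single call demonstrates
(and a single test verifies) the whole analysis: the measured biochemical
trait and its best two-band spectral index are each scanned with the Q+K
mixed model, and the comparison checks that the index recovers the gene(s)
harbouring the planted causal markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import popgen, trait_qc
from .compare_annotate import TraitComparison, compare_traits
from .gwas_mlm import GwasResults, MixedLMGwas
from .index_search import IndexSearchResults, TwoBandIndexModel
from .io_formats import GeneModel, GenotypeMatrix
from .spectra_preprocess import SpectraSet, average_replicates, calibrate, trim_bands
from .synthetic_data import (
    SimulationConfig,
    SyntheticTruth,
    simulate_population,
    simulate_spectra,
    simulate_trait,
)

__all__ = ["PipelineResult", "run_pipeline", "synthetic_gene_models"]


def synthetic_gene_models(
    variants: pd.DataFrame,
    causal_indices: np.ndarray,
    span_bp: int = 4_000,
    every: int = 5,
) -> list[GeneModel]:
    """Synthetic gene models tiling the marker panel (labelled as such).

    A gene span is placed around every ``every``-th marker and around every
    causal marker; causal genes are labelled ``"causal"`` so comparisons
    can check their recovery.
    """
    causal = set(int(i) for i in causal_indices)
    genes = []
    for j in sorted(set(range(0, len(variants), every)) | causal):
        row = variants.iloc[j]
        label = "causal" if j in causal else ""
        genes.append(
            GeneModel(
                gene_id=f"G{row.chrom}_{int(row.pos)}",
                chrom=str(row.chrom),
                start=max(1, int(row.pos) - span_bp // 2),
                end=int(row.pos) + span_bp // 2,
                label=label,
            )
        )
    return genes


@dataclass
class PipelineResult:
    """Everything the end-to-end run produced."""

    config: SimulationConfig
    truth: SyntheticTruth
    trait: pd.Series
    trait_summary: trait_qc.TraitSummary
    spectra: SpectraSet
    index_results: IndexSearchResults
    hyperspectral_trait: pd.Series
    genotypes: GenotypeMatrix
    variants: pd.DataFrame
    kinship: pd.DataFrame
    pcs: pd.DataFrame
    gwas_trait: GwasResults
    gwas_index: GwasResults
    gene_models: list[GeneModel]
    comparison: TraitComparison

    def summary(self) -> str:
        sel = self.index_results.selected()
        parts = [
            f"samples {self.config.n_samples}, markers kept {self.genotypes.n_markers}",
            f"trait mean {self.trait_summary.mean:.2f}, sd {self.trait_summary.sd:.2f}, "
            f"cv {self.trait_summary.cv_display:.2f} ({self.trait_summary.verdict})",
            f"selected index {sel.definition.kind}: {sel.formula} (R^2 = {sel.r2:.3f})",
            self.gwas_trait.summary(),
            self.gwas_index.summary(),
            self.comparison.summary(),
        ]
        return "\n\n".join(parts)


def run_pipeline(
    cfg: SimulationConfig | None = None,
    q_pcs: int = 5,
    index_stride: int = 1,
) -> PipelineResult:
    """Run the full synthetic analysis from one configuration and seed."""
    cfg = cfg or SimulationConfig()

    # 1. simulate genotypes, trait, raw spectra
    genotypes, variants, labels = simulate_population(cfg)
    trait, truth = simulate_trait(genotypes, cfg, subpop_labels=labels)
    frames = simulate_spectra(trait, cfg)

    # 2. preprocess spectra: calibrate -> trim -> average replicates
    cal = calibrate(frames.raw, frames.white, frames.dark)
    spectra = average_replicates(trim_bands(cal))

    # 3. trait QC
    summary = trait_qc.summarize_trait(trait.to_numpy(), name=str(trait.name))
    summary.normality_p, summary.verdict = trait_qc.normality_gate(trait.to_numpy())

    # 4. two-band index search and selection
    index_results = TwoBandIndexModel(spectra, trait).fit(stride=index_stride)
    hyper = index_results.hyperspectral_trait()
    best_r2 = index_results.selected().r2
    status = trait_qc.eligibility(summary, best_r2)
    if status != "gwas-eligible":
        raise RuntimeError(
            f"trait not eligible for association testing (status: {status})"
        )

    # 5. population-structure quantities
    genotypes_f, variants_f, keep = popgen.maf_filter(genotypes, variants)
    K = popgen.kinship(genotypes_f)
    Q = popgen.pca_covariates(genotypes_f, q=min(q_pcs, cfg.k_subpops - 1))

    # remap causal indices onto the filtered panel
    kept_idx = np.flatnonzero(keep)
    remap = {int(old): new for new, old in enumerate(kept_idx)}
    causal_kept = np.array(
        [remap[int(i)] for i in truth.causal_indices if int(i) in remap], dtype=int
    )

    # 6. mixed-model scans for the measured trait and its spectral proxy
    # LOCO kinship: with few strong causal loci at this panel size, the
    # tested marker's own contribution to K otherwise absorbs its signal
    gwas_trait = MixedLMGwas(trait, genotypes_f, K, Q=Q, variants=variants_f).fit(loco=True)
    gwas_index = MixedLMGwas(hyper, genotypes_f, K, Q=Q, variants=variants_f).fit(loco=True)

    # 7. gene lookup and trait-vs-trait comparison
    genes = synthetic_gene_models(variants_f, causal_kept)
    comparison = compare_traits(
        gwas_index, gwas_trait, genes, name_a=str(hyper.name), name_b=str(trait.name)
    )

    truth.causal_indices = causal_kept
    return PipelineResult(
        config=cfg,
        truth=truth,
        trait=trait,
        trait_summary=summary,
        spectra=spectra,
        index_results=index_results,
        hyperspectral_trait=hyper,
        genotypes=genotypes_f,
        variants=variants_f,
        kinship=K,
        pcs=Q,
        gwas_trait=gwas_trait,
        gwas_index=gwas_index,
        gene_models=genes,
        comparison=comparison,
    )
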