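"""Map significant loci to gene models and compare two traits' scans.

The comparison emulates checking whether a proxy trait (a spectral index)
recovers the same association signal as the directly measured trait: SNP
sets are compared by (chrom, pos), gene sets by gene id, and a superset
verdict records whether trait A's genes cover trait B's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import GeneModel

__all__ = ["TraitComparison", "genes_in_intervals", "compare_traits"]


def genes_in_intervals(
    intervals: pd.DataFrame, gene_models: list[GeneModel]
) -> dict[tuple, list[GeneModel]]:
    """Genes overlapping each locus interval by >= 1 bp (both 1-based inclusive).

    Keys are ``(chrom, start, end)`` tuples; gene lists sort by position.
    A chromosome name present in intervals but absent from the gene models
    is an error (guards against assembly-name mismatches).
    """
    gene_chroms = {g.chrom for g in gene_models}
    unmatched = sorted(set(intervals.chrom.astype(str)) - gene_chroms) if len(intervals) else []
    if unmatched and gene_models:
        raise ValueError(
            f"interval chromosomes absent from gene models: {unmatched}"
        )
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
    out: dict[tuple, list[GeneModel]] = {}
    for row in intervals.itertuples(index=False):
        key = (str(row.chrom), int(row.start), int(row.end))
        hits = [
            g
            for g in by_chrom.get(str(row.chrom), [])
            if g.start <= key[2] and g.end >= key[1]  # inclusive overlap >= 1 bp
        ]
        out[key] = hits
    return out


@dataclass
class TraitComparison:
    """Venn-style comparison of two scans' SNPs and located genes."""

    name_a: str
    name_b: str
    snps_shared: set = field(default_factory=set)
    snps_only_a: set = field(default_factory=set)
    snps_only_b: set = field(default_factory=set)
    genes_a: set = field(default_factory=set)
    genes_b: set = field(default_factory=set)

    @property
    def genes_shared(self) -> set:
        return self.genes_a & self.genes_b

    @property
    def genes_only_a(self) -> set:
        return self.genes_a - self.genes_b

    @property
    def genes_only_b(self) -> set:
        return self.genes_b - self.genes_a

    @property
    def a_covers_b(self) -> bool:
        """Does trait A's gene set contain every gene trait B found?"""
        return self.genes_b <= self.genes_a

    def venn_counts(self) -> dict[str, int]:
        return {
            "snps_shared": len(self.snps_shared),
            "snps_only_a": len(self.snps_only_a),
            "snps_only_b": len(self.snps_only_b),
            "genes_shared": len(self.genes_shared),
            "genes_only_a": len(self.genes_only_a),
            "genes_only_b": len(self.genes_only_b),
        }

    def summary(self) -> str:
        c = self.venn_counts()
        return "\n".join(
            [
                f"Trait comparison: {self.name_a} vs {self.name_b}",
                f"  SNPs   shared {c['snps_shared']}, "
                f"{self.name_a}-only {c['snps_only_a']}, "
                f"{self.name_b}-only {c['snps_only_b']}",
                f"  genes  shared {c['genes_shared']}, "
                f"{self.name_a}-only {c['genes_only_a']}, "
                f"{self.name_b}-only {c['genes_only_b']}",
                f"  {self.name_a} covers {self.name_b}: {self.a_covers_b}",
            ]
        )


def compare_traits(
    result_a,
    result_b,
    gene_models: list[GeneModel],
    name_a: str = "A",
    name_b: str = "B",
) -> TraitComparison:
    """Compare two scans from the same marker panel.

    Significant SNPs are matched by (chrom, pos); genes found in either
    scan's locus intervals by gene id.
    """
    snps_a = {(str(r.chrom), int(r.pos)) for r in result_a.significant.itertuples()}
    snps_b = {(str(r.chrom), int(r.pos)) for r in result_b.significant.itertuples()}

    def _genes(result) -> set:
        if result.loci is None or result.loci.empty:
            return set()
        hits = genes_in_intervals(result.loci, gene_models)
        return {g.gene_id for lst in hits.values() for g in lst}

    return TraitComparison(
        name_a=name_a,
        name_b=name_b,
        snps_shared=snps_a & snps_b,
        snps_only_a=snps_a - snps_b,
        snps_only_b=snps_b - snps_a,
        genes_a=_genes(result_a),
        genes_b=_genes(result_b),
    )
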