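"""HPO-guided gene-level enrichment of association signal.

For each gene in the region, traits split into two groups: those linked to
the gene by the (static) HPO gene-to-trait map, and traits linked to other
region genes but not to this one.  For every probe inside the gene window
(gene span ± 10 kb) a one-sided Wilcoxon rank-sum test asks whether the
linked traits' association p values are smaller than the unlinked traits'.
Gene-level significance uses a gene-specific effective-test threshold
(0.05 / N_eff of the gene's probe correlation matrix), and the number of
significant genes is summarised by an upper-tail exact binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cnv_matrix import CnvMatrix, probe_correlation
from .scan import effective_tests
from .sensitivity import wilcoxon_rank_sum

#: Minimum traits per group for a gene to enter the comparison.
MIN_CONTINUOUS = 4
MIN_BINARY = 10

GENE_WINDOW = 10_000


@dataclass
class GeneTraitGroups:
    gene: str
    window: tuple
    linked_traits: list = field(default_factory=list)
    unlinked_traits: list = field(default_factory=list)
    eligible_continuous: bool = False
    eligible_binary: bool = False


def group_traits(gene: str, hpo_map: pd.DataFrame, traits: pd.DataFrame,
                 gene_annotation: pd.DataFrame, window: int = GENE_WINDOW) -> GeneTraitGroups:
    """Partition traits into HPO-linked vs unlinked for one focal gene.

    ``hpo_map`` holds columns (gene, trait); ``traits`` columns
    (trait, kind) with kind in {continuous, binary}; ``gene_annotation``
    columns (gene, chrom, start, end).  Unlinked traits are those linked to
    at least one other region gene but not to the focal gene.
    """
    ann = gene_annotation.set_index("gene")
    if gene not in ann.index:
        raise ValueError(f"gene {gene!r} absent from annotation")
    start, end = int(ann.loc[gene, "start"]), int(ann.loc[gene, "end"])

    linked = set(hpo_map.loc[hpo_map["gene"] == gene, "trait"])
    mapped_any = set(hpo_map["trait"])
    unlinked = (mapped_any - linked) & set(traits["trait"])
    linked &= set(traits["trait"])

    kind = traits.set_index("trait")["kind"]
    n_cont = min(sum(kind[t] == "continuous" for t in linked),
                 sum(kind[t] == "continuous" for t in unlinked))
    n_bin = min(sum(kind[t] == "binary" for t in linked),
                sum(kind[t] == "binary" for t in unlinked))
    return GeneTraitGroups(
        gene=gene,
        window=(start - window, end + window),
        linked_traits=sorted(linked),
        unlinked_traits=sorted(unlinked),
        eligible_continuous=n_cont >= MIN_CONTINUOUS,
        eligible_binary=n_bin >= MIN_BINARY,
    )


def gene_wilcoxon(assoc: pd.DataFrame, groups: GeneTraitGroups, model: str,
                  trait_kind: str | None = None) -> pd.DataFrame:
    """Per-probe one-sided Wilcoxon comparing linked vs unlinked p values.

    For each probe in the gene window, the association p values of the
    linked traits are compared with those of the unlinked traits under the
    alternative that linked traits have *smaller* p values.  Probes with an
    empty group after missing-value removal are skipped.
    """
    sub = assoc[(assoc["model"] == model)
                & (assoc["bp"] >= groups.window[0])
                & (assoc["bp"] <= groups.window[1])]
    rows = []
    for probe, grp in sub.groupby("probe_id", sort=False):
        pv = grp.set_index("trait")["p"]
        linked = pv.reindex(groups.linked_traits).dropna().to_numpy()
        unlinked = pv.reindex(groups.unlinked_traits).dropna().to_numpy()
        if linked.size == 0 or unlinked.size == 0:
            continue
        p = wilcoxon_rank_sum(linked, unlinked, alternative="less")
        rows.append({"gene": groups.gene, "probe_id": probe, "model": model,
                     "trait_kind": trait_kind, "wilcoxon_p": p,
                     "n_linked": linked.size, "n_unlinked": unlinked.size})
    return pd.DataFrame(rows, columns=["gene", "probe_id", "model", "trait_kind",
                                       "wilcoxon_p", "n_linked", "n_unlinked"])


def gene_verdict(probe_pvalues, gene_probe_corr: np.ndarray, alpha_base: float = 0.05) -> dict:
    """Gene-level significance with a gene-specific effective-test threshold.

    ``gene_probe_corr`` is the correlation matrix of the gene-window probes'
    copy-number states; the threshold is ``alpha_base / N_eff(gene)`` and
    the gene is significant when its smallest probe-level Wilcoxon p
    reaches it.
    """
    pv = np.asarray(probe_pvalues, dtype=float)
    pv = pv[~np.isnan(pv)]
    if pv.size == 0:
        raise ValueError("need at least one probe p value")
    neff = effective_tests(np.atleast_2d(gene_probe_corr))
    thr = alpha_base / neff
    return {
        "min_wilcoxon_p": float(pv.min()),
        "neff_gene": int(neff),
        "threshold": thr,
        "significant": bool(pv.min() <= thr),
    }


def binomial_enrichment(n_significant: int, n_genes: int, p0: float = 0.05):
    """Fold enrichment and upper-tail exact binomial p for gene outcomes.

    ``fold = n_significant / (n_genes * p0)`` and
    ``p = P(X >= n_significant)`` for X ~ Binomial(n_genes, p0).
    """
    if not 0 <= n_significant <= n_genes:
        raise ValueError("need 0 <= n_significant <= n_genes")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    fold = n_significant / (n_genes * p0)
    p = float(stats.binom.sf(n_significant - 1, n_genes, p0)) if n_significant > 0 else 1.0
    return fold, p


def enrichment_analysis(
    assoc: pd.DataFrame,
    matrix: CnvMatrix,
    hpo_map: pd.DataFrame,
    traits: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    model: str,
    trait_kind: str,
    p0: float = 0.05,
    window: int = GENE_WINDOW,
) -> dict:
    """End-to-end enrichment for one (model, trait kind) analysis.

    Runs the grouping, per-probe Wilcoxon and gene verdicts over all
    eligible genes, then the binomial summary.  Returns a dict with the
    per-gene outcome table and the (n_genes, n_significant, fold, p) totals.
    """
    kind_traits = traits[traits["kind"] == trait_kind]
    assoc_k = assoc[assoc["trait"].isin(kind_traits["trait"])]
    outcomes = []
    for gene in gene_annotation["gene"]:
        groups = group_traits(gene, hpo_map, kind_traits, gene_annotation, window)
        eligible = groups.eligible_continuous if trait_kind == "continuous" else groups.eligible_binary
        if not eligible:
            continue
        per_probe = gene_wilcoxon(assoc_k, groups, model, trait_kind)
        if not len(per_probe):
            continue
        in_window = (matrix.probe_bp >= groups.window[0]) & (matrix.probe_bp <= groups.window[1])
        probe_ids = [p for p, m in zip(matrix.probe_ids, in_window) if m]
        sub = matrix.subset_probes(probe_ids)
        verdict = gene_verdict(per_probe["wilcoxon_p"], probe_correlation(sub))
        outcomes.append({"gene": gene, "model": model, "trait_kind": trait_kind, **verdict})
    genes_df = pd.DataFrame(outcomes)
    n_genes = len(genes_df)
    n_sig = int(genes_df["significant"].sum()) if n_genes else 0
    fold, p = binomial_enrichment(n_sig, n_genes, p0) if n_genes else (float("nan"), float("nan"))
    return {"genes": genes_df, "n_genes": n_genes, "n_significant": n_sig,
            "fold": fold, "binomial_p": p}
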