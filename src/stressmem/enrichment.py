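"""GO-term over-representation testing per module with FDR control.

For each term annotating at least ``min_mapped_entries`` reference genes,
a one-sided Fisher exact test (hypergeometric upper tail,
P(X >= k)) compares the term's frequency inside a module against the
reference gene set, and p values are Benjamini-Hochberg adjusted across
the terms tested within that module (per-module testing mirrors
per-gene-list web enrichment runs; a global adjustment is available).
Annotations are taken as provided — no GO-graph ancestor propagation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .io import AnnotationTable, log

__all__ = ["fisher_enrichment", "enrich_modules", "slim_rollup"]


def fisher_enrichment(
    module_genes: set[str],
    annotation: AnnotationTable,
    reference: set[str],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Over-representation of every eligible term in one gene set.

    Returns a DataFrame sorted by FDR with columns term, k (annotated in
    module), n (module size), K (annotated in reference), N (reference
    size), odds_ratio, p, fdr.  Terms with K < min_mapped_entries are
    not tested.
    """
    config = config or RunConfig()
    if not reference:
        raise ValueError("empty reference gene set")
    if not module_genes <= reference:
        raise ValueError("module genes must be a subset of the reference")
    N = len(reference)
    n = len(module_genes)
    rows = []
    for term, annotated in sorted(annotation.term_sets().items()):
        hits_ref = annotated & reference
        K = len(hits_ref)
        if K < config.min_mapped_entries:
            continue
        k = len(hits_ref & module_genes)
        # hypergeometric upper tail P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        a, b = k, n - k
        c, d = K - k, N - n - (K - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            {"term": term, "k": k, "n": n, "K": K, "N": N,
             "odds_ratio": odds, "p": min(p, 1.0)}
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "k", "n", "K", "N", "odds_ratio", "p", "fdr"]
        )
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values(["fdr", "p", "term"]).reset_index(drop=True)


def enrich_modules(
    partition_labels: pd.Series,
    annotation: AnnotationTable,
    config: RunConfig | None = None,
    reference: set[str] | None = None,
    global_fdr: bool = False,
) -> pd.DataFrame:
    """Per-module enrichment over a module assignment (0 = unassigned).

    ``partition_labels`` maps gene -> module id (or meta-module label).
    The reference defaults to all genes in the assignment.  With
    ``global_fdr`` the BH adjustment runs once across every
    (module, term) test instead of within each module.
    """
    reference = reference or set(partition_labels.index)
    frames = []
    for module in sorted({m for m in partition_labels.unique() if m != 0},
                         key=str):
        genes = set(partition_labels.index[partition_labels == module])
        res = fisher_enrichment(genes, annotation, reference, config)
        res.insert(0, "module", module)
        frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=["module", "term", "k", "n", "K", "N", "odds_ratio", "p", "fdr"]
        )
    out = pd.concat(frames, ignore_index=True)
    if global_fdr and len(out):
        out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values(["module", "fdr", "p", "term"]).reset_index(drop=True)
    log.info("enrichment: %d tests over %d modules", len(out),
             out["module"].nunique() if len(out) else 0)
    return out


def slim_rollup(
    results: pd.DataFrame, slim_map: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Collapse per-term enrichment to slim terms for heatmap export.

    For each (module, slim term) the minimum FDR among member terms is
    reported together with -log10(FDR); terms missing from the map fall
    into "other".
    """
    if isinstance(slim_map, pd.Series):
        slim_map = slim_map.to_dict()
    if results.empty:
        return pd.DataFrame(columns=["module", "slim_term", "fdr", "neg_log10_fdr"])
    df = results.copy()
    df["slim_term"] = df["term"].map(lambda t: slim_map.get(t, "other"))
    agg = (
        df.groupby(["module", "slim_term"], sort=True)["fdr"]
        .min()
        .reset_index()
    )
    with np.errstate(divide="ignore"):
        agg["neg_log10_fdr"] = -np.log10(agg["fdr"])
    return agg
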