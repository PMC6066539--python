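"""Differential-expression calls and stress-memory pattern classification.

A gene's behaviour over a repeated stress is summarised by a two-position
sign pattern.  The first sign is the first-stress response (S1 versus the
watered baseline W), the second the repeated-stress response (the repeated
stress versus S1): ``+`` significantly up, ``-`` significantly down, ``=``
no significant change.  Patterns partition into four categories:

* memory          — [+/+], [+/-], [-/-], [-/+]
* delayed-memory  — [=/+], [=/-]
* non-memory      — [+/=], [-/=]
* non-responsive  — [=/=]

A contrast is significant only when all three conditions hold: BH-adjusted
q <= q_threshold, |log2 fold change| >= lfc_threshold, and at least one of
the two contrasted stage profiles exceeds that profile's expression-floor
percentile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .io import ExpressionStudy, log

__all__ = [
    "MEMORY_PATTERNS",
    "PATTERN_CATEGORY",
    "expression_floor",
    "call_differential",
    "classify_gene_memory",
    "classify_study",
    "pattern_label",
    "pattern_category",
]

MEMORY_PATTERNS = (
    "[+/+]", "[+/-]", "[-/-]", "[-/+]",
    "[=/+]", "[=/-]", "[+/=]", "[-/=]", "[=/=]",
)

PATTERN_CATEGORY = {
    "[+/+]": "memory",
    "[+/-]": "memory",
    "[-/-]": "memory",
    "[-/+]": "memory",
    "[=/+]": "delayed-memory",
    "[=/-]": "delayed-memory",
    "[+/=]": "non-memory",
    "[-/=]": "non-memory",
    "[=/=]": "non-responsive",
}


def pattern_label(first_sign: str, second_sign: str) -> str:
    for s in (first_sign, second_sign):
        if s not in "+-=" or len(s) != 1:
            raise ValueError(f"invalid sign {s!r}")
    return f"[{first_sign}/{second_sign}]"


def pattern_category(pattern: str) -> str:
    return PATTERN_CATEGORY[pattern]


def expression_floor(
    study: ExpressionStudy, contrast: tuple[str, str], percentile: float
) -> pd.Series:
    """Expression floor of the differential-expression triple rule.

    True for a gene iff, in at least one of the two contrasted stage-mean
    profiles, its FPKM strictly exceeds that profile's given percentile
    computed over all genes (linear interpolation between order
    statistics).  Filters out genes expressed near zero in both samples.
    """
    if study.fpkm.empty:
        raise ValueError("empty expression matrix")
    means = study.stage_means()
    cols = []
    for stage in contrast:
        if stage not in means.columns:
            raise ValueError(f"stage {stage!r} absent from study")
        profile = means[stage]
        floor = np.percentile(profile.to_numpy(), percentile)
        cols.append(profile > floor)
    return (cols[0] | cols[1]).rename("passes_floor")


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene variances toward a common prior.

    Fits a scaled inverse-chi-square prior (s0^2, d0) to the observed
    variances by the method of moments on log(s^2) and returns the
    posterior variances (d0*s0^2 + df*s^2)/(d0 + df) and the prior df d0
    (inf when the observed variances are no more dispersed than sampling
    alone explains).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2, 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        d0 = np.inf
        s02 = float(np.exp(e_mean))
        post = np.full_like(s2, s02)
        post[~ok] = s02
        return post, d0
    # invert trigamma by Newton iteration (y = trigamma(x))
    y = e_var
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s02 = float(np.exp(e_mean + special.digamma(x) - np.log(x)))
    post = (d0 * s02 + df * s2) / (d0 + df)
    return post, d0


def _signed_inf(d):
    return np.where(d == 0, 0.0, np.where(d > 0, np.inf, -np.inf))


def _welch_p(mean_diff, v1, n1, v2, n2):
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / np.sqrt(se2)
        dfn = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    t = np.where(se2 == 0, _signed_inf(mean_diff), t)
    dfn = np.where(np.isfinite(dfn), dfn, 1.0)
    p = 2.0 * stats.t.sf(np.abs(t), dfn)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se2 == 0) & (mean_diff == 0), 1.0, p)
    return t, p


def call_differential(
    study: ExpressionStudy,
    contrast: tuple[str, str],
    config: RunConfig | None = None,
    external: pd.DataFrame | None = None,
    moderate_var: bool = True,
) -> pd.DataFrame:
    """Per-gene differential call for ``contrast = (treatment, baseline)``.

    Returns a DataFrame indexed by gene with columns ``log2_fc``,
    ``p_value``, ``q_value``, ``passes_floor`` and ``significant``.

    The internal test path computes log2_fc = log2((mean FPKM_t + 1) /
    (mean FPKM_b + 1)) and a two-sided Welch t on log2(FPKM + 1)
    replicates; with ``moderate_var`` (default) the per-gene pooled
    residual variance is shrunk toward an empirical-Bayes prior shared
    across genes before the t statistic is formed, which stabilises the
    test at two replicates per stage.  q values are Benjamini-Hochberg
    adjusted across genes.  Alternatively an ``external`` table with
    columns (gene, log2fc, q) supplies the statistics and only the floor
    rule is applied internally.
    """
    config = config or RunConfig()
    treat, base = contrast
    floor = expression_floor(study, contrast, config.expr_percentile)
    means = study.stage_means()
    log2_fc = np.log2((means[treat] + 1.0) / (means[base] + 1.0))

    if external is not None:
        ext = external.set_index("gene") if "gene" in external.columns else external
        missing = study.genes.difference(ext.index)
        if len(missing):
            raise ValueError(f"external DE table missing genes: {list(missing[:5])}")
        log2_fc = ext.loc[study.genes, "log2fc"].astype(float)
        q = ext.loc[study.genes, "q"].astype(float).to_numpy()
        p = q.copy()
    else:
        logm = study.log2_matrix()
        xt = logm[study.stage_samples(treat)].to_numpy()
        xb = logm[study.stage_samples(base)].to_numpy()
        n1, n2 = xt.shape[1], xb.shape[1]
        if min(n1, n2) < 2:
            raise ValueError(
                f"stage with a single replicate in contrast {contrast}; "
                "supply an external DE table"
            )
        d = xt.mean(axis=1) - xb.mean(axis=1)
        v1 = xt.var(axis=1, ddof=1)
        v2 = xb.var(axis=1, ddof=1)
        if moderate_var:
            df_res = n1 + n2 - 2
            s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_res
            s2_post, d0 = _squeeze_var(s2, df_res)
            se2 = s2_post * (1.0 / n1 + 1.0 / n2)
            df_t = df_res + (d0 if np.isfinite(d0) else 1e6)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = d / np.sqrt(se2)
            t = np.where(se2 == 0, _signed_inf(d), t)
            p = 2.0 * stats.t.sf(np.abs(t), df_t)
            p = np.where(np.isinf(t), 0.0, p)
            p = np.where((se2 == 0) & (d == 0), 1.0, p)
        else:
            _, p = _welch_p(d, v1, n1, v2, n2)
        q = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p_value": p,
            "q_value": q,
            "passes_floor": floor,
        },
        index=study.genes,
    )
    out["significant"] = (
        (out["q_value"] <= config.q_threshold)
        & (out["log2_fc"].abs() >= config.lfc_threshold)
        & out["passes_floor"]
    )
    log.info(
        "contrast %s vs %s: %d/%d significant", treat, base,
        int(out["significant"].sum()), len(out),
    )
    return out


@dataclass(frozen=True)
class MemoryCall:
    gene: str
    first_sign: str
    second_sign: str
    pattern: str
    category: str


def classify_gene_memory(call_s1: pd.Series, call_s3: pd.Series) -> MemoryCall:
    """Assemble one gene's memory pattern from its two contrast calls.

    ``call_s1`` / ``call_s3`` are rows of the first-stress and repeated-
    stress differential tables (need fields ``log2_fc`` and
    ``significant``).
    """
    def sign_of(call) -> str:
        if not bool(call["significant"]):
            return "="
        return "+" if call["log2_fc"] > 0 else "-"

    first, second = sign_of(call_s1), sign_of(call_s3)
    pat = pattern_label(first, second)
    return MemoryCall(str(call_s1.name), first, second, pat, PATTERN_CATEGORY[pat])


def classify_study(
    study: ExpressionStudy,
    config: RunConfig | None = None,
    external: dict[str, pd.DataFrame] | None = None,
    require_stable_repeat: bool = False,
    moderate_var: bool = True,
) -> pd.DataFrame:
    """Memory-pattern calls for every gene of a study.

    The first contrast is S1 vs W; the second is the repeated stress
    present in the design (S3 by default, reported as the S2 response
    under the declared stage equivalence) vs S1.  With
    ``require_stable_repeat`` and both repeated stresses present, the
    repeat response additionally requires no significant difference
    between the two repeated stresses.

    Returns a DataFrame indexed by gene with columns first_sign,
    second_sign, pattern, category, plus per-contrast statistics.
    """
    config = config or RunConfig()
    stages = [s for s in study.design.transcriptome_stages
              if (study.samples["stage"] == s).any()]
    if "W" not in stages or "S1" not in stages:
        raise ValueError("study must contain stages W and S1")
    repeat = next((s for s in stages if s not in ("W", "S1")), None)
    if repeat is None:
        raise ValueError("study lacks a repeated-stress stage")

    ext1 = external.get("S1-vs-W") if external else None
    ext2 = external.get(f"{repeat}-vs-S1") if external else None
    c1 = call_differential(study, ("S1", "W"), config, ext1, moderate_var)
    c2 = call_differential(study, (repeat, "S1"), config, ext2, moderate_var)

    if require_stable_repeat:
        repeats = [s for s in stages if s not in ("W", "S1")]
        if len(repeats) >= 2:
            c_rep = call_differential(study, (repeats[1], repeats[0]), config,
                                      moderate_var=moderate_var)
            c2 = c2.copy()
            c2["significant"] &= ~c_rep["significant"]

    first = np.where(c1["significant"], np.where(c1["log2_fc"] > 0, "+", "-"), "=")
    second = np.where(c2["significant"], np.where(c2["log2_fc"] > 0, "+", "-"), "=")
    pattern = pd.Series(
        [f"[{a}/{b}]" for a, b in zip(first, second)], index=study.genes
    )
    out = pd.DataFrame(
        {
            "first_sign": first,
            "second_sign": second,
            "pattern": pattern,
            "category": pattern.map(PATTERN_CATEGORY),
            "log2_fc_first": c1["log2_fc"],
            "q_first": c1["q_value"],
            "log2_fc_second": c2["log2_fc"],
            "q_second": c2["q_value"],
        },
        index=study.genes,
    )
    counts = out["category"].value_counts()
    log.info("memory classification: %s", counts.to_dict())
    return out
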