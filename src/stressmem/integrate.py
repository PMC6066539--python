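"""Eigengene-physiology correlation across dehydration stages.

Transcriptome samples and physiology plants are different individuals,
so the two data types are joined at the stage level: each parameter's
stage mean over plants is paired with every transcriptome sample of the
comparable stage (S2 physiology pairs with S3 transcriptome under the
declared equivalence; the rehydration stage R1 has no transcriptome
counterpart and is dropped).  Each module eigengene is then correlated
with each parameter over the paired samples (Pearson r with the
two-sided t-based p from t = r sqrt((n-2)/(1-r^2))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import StageDesign
from .io import PhysiologyTable
from .network import EigengeneSet

__all__ = ["ModuleTraitMatrix", "align_stages", "module_trait_correlation"]


def align_stages(
    eigs: EigengeneSet,
    phys: PhysiologyTable,
    design: StageDesign | None = None,
    stage_means_only: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair eigengenes with physiology over comparable stages.

    Returns ``(eig_paired, trait_paired)``: eigengene values
    (modules x paired points) and parameter values (parameters x paired
    points).  By default each physiology stage mean is replicated to
    every transcriptome sample of the matching stage (n = 6 points for
    the 3-stage, 2-replicate design); with ``stage_means_only`` each
    stage contributes a single point.
    """
    design = design or StageDesign()
    sample_stage = _sample_stages(eigs, design)
    # physiology stage -> matching transcriptome stage actually sampled
    stage_pairs = []
    tstages = set(sample_stage.values())
    present = set(phys.data["stage"])
    for ps in design.physiology_stages:
        if ps not in present:
            continue
        ts = ps if ps in tstages else design.equivalent(ps)
        if ts in tstages:
            stage_pairs.append((ts, ps))
    if not stage_pairs:
        raise ValueError("no overlapping stages between eigengenes and physiology")

    columns: list[str] = []
    trait_rows: dict[str, list[float]] = {p: [] for p in phys.parameters}
    eig_cols: list[str] = []
    for ts, ps in stage_pairs:
        samples = [s for s, st in sample_stage.items() if st == ts]
        take = samples[:1] if stage_means_only else samples
        for s in take:
            eig_cols.append(s)
            columns.append(f"{s}|{ps}")
            for p in phys.parameters:
                trait_rows[p].append(float(np.mean(phys.values_for(p, ps))))

    eig_paired = eigs.eigengenes[eig_cols].copy()
    eig_paired.columns = columns
    trait_paired = pd.DataFrame(trait_rows, index=columns).T
    trait_paired.index.name = "parameter"
    return eig_paired, trait_paired


def _sample_stages(eigs: EigengeneSet, design: StageDesign) -> dict[str, str]:
    """Infer each eigengene sample's stage from its name or sheet-style label.

    Sample names produced by this package are ``<stage>_r<replicate>``;
    a name equal to a stage label is also accepted.
    """
    out = {}
    for s in eigs.eigengenes.columns:
        stage = s.split("_")[0]
        if stage not in design.transcriptome_stages:
            raise ValueError(f"cannot infer stage of sample {s!r}")
        out[s] = stage
    return out


@dataclass
class ModuleTraitMatrix:
    """Module x parameter grid of (Pearson r, two-sided p)."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def long(self) -> pd.DataFrame:
        rows = []
        for m in self.r.index:
            for param in self.r.columns:
                rows.append(
                    {"module": m, "parameter": param,
                     "r": self.r.loc[m, param], "p": self.p.loc[m, param]}
                )
        return pd.DataFrame(rows)


def module_trait_correlation(
    eig_paired: pd.DataFrame,
    trait_paired: pd.DataFrame,
    adjust_fdr: bool = False,
) -> ModuleTraitMatrix:
    """Pearson correlation of every module eigengene with every parameter.

    Constant trait vectors yield undefined (NaN) cells rather than zero.
    With ``adjust_fdr`` the p grid is BH-adjusted across all defined
    cells (off by default: the raw per-cell p values are reported).
    """
    n = eig_paired.shape[1]
    if n < 3:
        raise ValueError("need >= 3 paired points")
    if list(eig_paired.columns) != list(trait_paired.columns):
        raise ValueError("eigengene and trait pairings disagree")
    r = pd.DataFrame(index=eig_paired.index, columns=trait_paired.index, dtype=float)
    p = r.copy()
    for m in eig_paired.index:
        x = eig_paired.loc[m].to_numpy(dtype=float)
        for param in trait_paired.index:
            y = trait_paired.loc[param].to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(x) == 0:
                r.loc[m, param] = np.nan
                p.loc[m, param] = np.nan
                continue
            rv = float(np.corrcoef(x, y)[0, 1])
            rv = max(-1.0, min(1.0, rv))
            if abs(rv) == 1.0:
                pv = 0.0
            else:
                t = rv * np.sqrt((n - 2) / (1.0 - rv**2))
                pv = float(2.0 * stats.t.sf(abs(t), n - 2))
            r.loc[m, param] = rv
            p.loc[m, param] = pv
    if adjust_fdr:
        flat = p.to_numpy().ravel()
        ok = np.isfinite(flat)
        adj = flat.copy()
        adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        p = pd.DataFrame(adj.reshape(p.shape), index=p.index, columns=p.columns)
    return ModuleTraitMatrix(r, p, n)
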