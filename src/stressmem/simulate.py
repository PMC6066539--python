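"""Synthetic expression, annotation and physiology data with planted truth.

The generator emulates the study design the analysis assumes: a small
FPKM matrix over stages W, S1 and a repeated stress S3 with two
biological replicates each, block-correlated gene modules that each
follow a planted stage profile and memory pattern, lognormal replicate
noise (Gaussian on the log2(FPKM+1) scale), planted GO-term enrichments,
and stage-structured physiology with Gaussian plant-to-plant noise whose
default stage means encode the qualitative memory calls of the original
experiment (e.g. stomatal conductance [-/-], RWC [-/=], ABA [+/=],
net photosynthesis [=/-], energy-dependent quenching [=/+]).

Module stage profiles are mean log2-expression at (W, S1, S3); a gene in
a module has log2(FPKM+1) = loading x profile(stage) + N(0,
replicate_sd) with gene-specific positive loadings, so module mates
share a correlation direction.  Because the downstream network is
unsigned (1 - |r|), a profile and its mirror image are
indistinguishable; the default five profiles are chosen with pairwise
|r| <= 0.87 and no mirror pairs, which the default tree cut separates.
Background genes are i.i.d. noise around flat gene-specific levels.

All randomness flows from one integer seed through numpy's PCG64
generator, so outputs are bit-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StageDesign
from .io import AnnotationTable, ExpressionStudy, PhysiologyTable
from .memory import MEMORY_PATTERNS

__all__ = [
    "ModulePlan",
    "SimulationSpec",
    "SyntheticTruth",
    "default_physiology_plan",
    "simulate_expression",
    "simulate_annotations",
    "simulate_physiology",
    "simulate_raw_fluorescence",
]


@dataclass(frozen=True)
class ModulePlan:
    """One planted module: size, stage profile and declared pattern."""

    size: int
    stage_profile: tuple[float, float, float]  # mean log2 expr at (W, S1, S3)
    memory_pattern: str  # one of the 9 two-sign labels


#: five well-separated default profiles (baseline log2 level 6, effects 2x
#: the |log2FC| >= 1 significance threshold)
DEFAULT_MODULES = (
    ModulePlan(50, (6.0, 8.0, 10.0), "[+/+]"),
    ModulePlan(50, (6.0, 8.0, 6.0), "[+/-]"),
    ModulePlan(50, (6.0, 6.0, 8.0), "[=/+]"),
    ModulePlan(50, (6.0, 4.0, 4.0), "[-/=]"),
    ModulePlan(50, (6.0, 10.0, 8.0), "[+/-]"),
)


def default_physiology_plan(
    ppfd: float = 1500.0,
    r_d: float = 1.0,
    absorptance: float = 0.85,
    psii_fraction: float = 0.5,
    noise_frac: float = 0.08,
) -> dict[str, tuple[tuple[float, float, float, float], float]]:
    """Stage means (W, S1, R1, S2) and plant-to-plant sd per parameter.

    Directly planted: RWC, ABA, gas exchange, chlorophyll, phiPSII, qP,
    NPQ, qE.  The remaining parameters are computed from those through
    the same closed-form identities the derivation module uses, so the
    planted table is internally consistent.  Stages carrying an "="
    contrast share exactly equal means so the zero-noise limit is
    well-defined.  The default sd is ``noise_frac`` of the watered mean.
    """
    base = {
        "RWC": (98.0, 80.0, 97.0, 80.0),
        "ABA": (20.0, 200.0, 45.0, 200.0),
        "g_s": (150.0, 60.0, 100.0, 30.0),
        "E": (4.0, 1.6, 2.8, 0.8),
        "P_N": (30.0, 30.0, 28.0, 10.0),
        "C_i": (180.0, 120.0, 130.0, 120.0),
        "chlorophyll": (9.0, 7.5, 6.5, 5.0),
        "phiPSII": (0.60, 0.60, 0.58, 0.30),
        "qP": (0.85, 0.85, 0.83, 0.55),
        "NPQ": (0.40, 0.40, 0.60, 1.90),
        "qE": (0.20, 0.20, 0.35, 1.50),
    }
    phi = np.array(base["phiPSII"])
    qp = np.array(base["qP"])
    npq = np.array(base["NPQ"])
    qe = np.array(base["qE"])
    p_n = np.array(base["P_N"])
    a_g = p_n + r_d
    etr = phi * ppfd * psii_fraction * absorptance
    phi_co2 = a_g / (ppfd * absorptance)
    derived = {
        "ETR": etr,
        "FvFm_prime": phi / qp,
        "phiCO2": phi_co2,
        "A_G": a_g,
        "phi_qE": (1.0 - phi) * qe / (npq + 1.0),
        "qE/ETR": qe / etr,
        "phiPSII/phiCO2": phi / phi_co2,
        "ETR/A_G": etr / a_g,
    }
    plan = {}
    for name, means in {**base, **{k: tuple(v) for k, v in derived.items()}}.items():
        sd = noise_frac * abs(means[0])
        plan[name] = (tuple(float(m) for m in means), sd)
    return plan


#: qualitative pattern each default parameter plan encodes (zero-noise calls)
DEFAULT_PHYSIOLOGY_PATTERNS = {
    "RWC": "[-/=]",
    "ABA": "[+/=]",
    "g_s": "[-/-]",
    "E": "[-/-]",
    "P_N": "[=/-]",
    "C_i": "[-/=]",
    "chlorophyll": "[-/-]",
    "phiPSII": "[=/-]",
    "qP": "[=/-]",
    "ETR": "[=/-]",
    "FvFm_prime": "[=/-]",
    "phiCO2": "[=/-]",
    "A_G": "[=/-]",
    "NPQ": "[=/+]",
    "qE": "[=/+]",
    "phi_qE": "[=/+]",
    "qE/ETR": "[=/+]",
    "phiPSII/phiCO2": "[=/+]",
    "ETR/A_G": "[=/+]",
}


@dataclass
class SimulationSpec:
    """Everything the generator needs, with the study's default conditions."""

    n_genes: int = 2000
    modules: tuple[ModulePlan, ...] = DEFAULT_MODULES
    n_replicates: int = 2
    replicate_sd: float = 0.1
    loading_sd: float = 0.15
    background_level_range: tuple[float, float] = (1.0, 5.0)
    effect_threshold: float = 1.0  # |log2FC| scale for pattern consistency
    #: (module, term, odds) triples; None plants one term per module at odds 8
    enrichment_plan: tuple[tuple[int, str, float], ...] | None = None
    annotation_baseline: float = 0.05
    n_null_terms: int = 20
    physiology_plan: dict = field(default_factory=default_physiology_plan)
    physiology_patterns: dict = field(
        default_factory=lambda: dict(DEFAULT_PHYSIOLOGY_PATTERNS)
    )
    n_plants: int = 10
    ppfd: float = 1500.0
    r_d: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment_plan is None:
            self.enrichment_plan = tuple(
                (i, f"GO:{i:04d}", 8.0) for i in range(1, len(self.modules) + 1)
            )
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if self.replicate_sd < 0 or self.loading_sd < 0:
            raise ValueError("noise scales must be non-negative")
        for i, m in enumerate(self.modules, start=1):
            if m.memory_pattern not in MEMORY_PATTERNS:
                raise ValueError(f"unknown pattern {m.memory_pattern!r}")
            _check_profile(i, m, self.effect_threshold)
        for mod, term, odds in self.enrichment_plan:
            if not 1 <= mod <= len(self.modules):
                raise ValueError(f"enrichment plan names unknown module {mod}")
            if odds <= 0:
                raise ValueError(f"odds must be positive, got {odds} for {term}")
        for name, (_means, sd) in self.physiology_plan.items():
            if sd < 0:
                raise ValueError(f"negative sd for parameter {name!r}")


def _check_profile(idx: int, m: ModulePlan, thr: float) -> None:
    """A planted profile must realise its declared pattern with margin
    at least the effect threshold on each non-'=' leg and stay strictly
    below it on each '=' leg."""
    w, s1, s3 = m.stage_profile
    deltas = {"first": s1 - w, "second": s3 - s1}
    signs = m.memory_pattern[1], m.memory_pattern[3]
    for (leg, d), s in zip(deltas.items(), signs):
        ok = (
            (s == "+" and d >= thr)
            or (s == "-" and d <= -thr)
            or (s == "=" and abs(d) < thr)
        )
        if not ok:
            raise ValueError(
                f"module {idx}: {leg} profile step {d:+.2f} contradicts "
                f"declared pattern {m.memory_pattern}"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth keyed like the analysis outputs."""

    gene_module: pd.Series  # gene -> module id (0 = background)
    gene_pattern: pd.Series  # gene -> memory pattern label
    enriched_terms: dict[int, list[str]]  # module -> planted terms
    parameter_pattern: dict[str, str]  # physiology parameter -> pattern

    def __post_init__(self) -> None:
        if not self.gene_module.index.equals(self.gene_pattern.index):
            raise ValueError("truth labels must cover every simulated gene")


def _stage_columns(design: StageDesign, n_rep: int) -> list[tuple[str, int]]:
    return [(s, r) for s in design.transcriptome_stages for r in range(1, n_rep + 1)]


def simulate_expression(
    spec: SimulationSpec, design: StageDesign | None = None
) -> tuple[ExpressionStudy, SyntheticTruth]:
    """Simulate the FPKM matrix and its planted truth."""
    design = design or StageDesign()
    rng = np.random.default_rng(spec.seed)
    cols = _stage_columns(design, spec.n_replicates)
    sample_names = [f"{s}_r{r}" for s, r in cols]
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]

    n_mod = sum(m.size for m in spec.modules)
    module_of = np.zeros(spec.n_genes, dtype=int)
    pattern = np.array(["[=/=]"] * spec.n_genes, dtype=object)
    log2x = np.empty((spec.n_genes, len(cols)))

    pos = 0
    for mid, m in enumerate(spec.modules, start=1):
        idx = slice(pos, pos + m.size)
        module_of[pos:pos + m.size] = mid
        pattern[pos:pos + m.size] = m.memory_pattern
        loadings = rng.normal(1.0, spec.loading_sd, m.size).clip(0.5, 1.5)
        prof = dict(zip(design.transcriptome_stages, m.stage_profile))
        means = np.array([[l * prof[s] for s, _ in cols] for l in loadings])
        log2x[idx] = means + rng.normal(0.0, spec.replicate_sd, (m.size, len(cols)))
        pos += m.size

    lo, hi = spec.background_level_range
    bg_levels = rng.uniform(lo, hi, spec.n_genes - n_mod)
    log2x[n_mod:] = bg_levels[:, None] + rng.normal(
        0.0, spec.replicate_sd, (spec.n_genes - n_mod, len(cols))
    )

    fpkm = np.maximum(np.exp2(log2x) - 1.0, 0.0)
    mat = pd.DataFrame(fpkm, index=pd.Index(genes, name="gene"), columns=sample_names)
    sheet = pd.DataFrame(
        {"stage": [s for s, _ in cols], "replicate": [r for _, r in cols]},
        index=pd.Index(sample_names, name="sample"),
    )
    study = ExpressionStudy(mat, sheet, design)
    truth = SyntheticTruth(
        pd.Series(module_of, index=genes, name="module"),
        pd.Series(pattern, index=genes, name="pattern"),
        _enrichment_truth(spec),
        dict(spec.physiology_patterns),
    )
    return study, truth


def _enrichment_truth(spec: SimulationSpec) -> dict[int, list[str]]:
    out: dict[int, list[str]] = {}
    for mod, term, _odds in spec.enrichment_plan:
        out.setdefault(mod, []).append(term)
    return out


def simulate_annotations(
    spec: SimulationSpec, truth: SyntheticTruth
) -> AnnotationTable:
    """Annotate genes so planted (module, term) pairs are over-represented.

    For a planned (module, term, odds): genes inside the module carry the
    term with probability min(odds x baseline, 1) — ``odds = inf`` means
    every module gene is annotated — genes outside with the baseline
    probability.  ``n_null_terms`` additional terms annotate uniformly at
    the baseline.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = truth.gene_module.index.to_numpy()
    in_module = {
        mod: (truth.gene_module == mod).to_numpy()
        for mod, _, _ in spec.enrichment_plan
    }
    rows: list[tuple[str, str]] = []
    base = spec.annotation_baseline
    for mod, term, odds in spec.enrichment_plan:
        p_in = 1.0 if np.isinf(odds) else min(odds * base, 1.0)
        p = np.where(in_module[mod], p_in, base)
        hit = rng.random(len(genes)) < p
        rows += [(g, term) for g in genes[hit]]
    for j in range(spec.n_null_terms):
        term = f"GO:{100 + j:04d}"
        hit = rng.random(len(genes)) < base
        rows += [(g, term) for g in genes[hit]]
    return AnnotationTable(pd.DataFrame(rows, columns=["gene", "term"]))


def simulate_physiology(
    spec: SimulationSpec, design: StageDesign | None = None
) -> tuple[PhysiologyTable, SyntheticTruth]:
    """Per-plant physiology: stage mean + Gaussian plant-to-plant noise."""
    design = design or StageDesign()
    if spec.n_plants < 2:
        raise ValueError("need >= 2 plants per stage")
    rng = np.random.default_rng(spec.seed + 2)
    records = []
    for name, (means, sd) in spec.physiology_plan.items():
        for stage, mu in zip(design.physiology_stages, means):
            vals = mu + rng.normal(0.0, sd, spec.n_plants)
            for i, v in enumerate(vals, start=1):
                records.append(
                    {"plant_id": f"p{i:02d}", "stage": stage,
                     "parameter": name, "value": v}
                )
    table = PhysiologyTable(pd.DataFrame(records), design)
    genes = pd.Index([], dtype=object)
    truth = SyntheticTruth(
        pd.Series([], index=genes, dtype=int, name="module"),
        pd.Series([], index=genes, dtype=object, name="pattern"),
        _enrichment_truth(spec),
        dict(spec.physiology_patterns),
    )
    return table, truth


def simulate_raw_fluorescence(
    spec: SimulationSpec,
    design: StageDesign | None = None,
    fm: float = 4000.0,
) -> pd.DataFrame:
    """Raw PAM records consistent with the planted fluorescence targets.

    Per plant x stage the planted phiPSII, qP, NPQ and qE (stage mean +
    noise) are inverted through the closed-form identities:
    Fm' = Fm/(1+NPQ), Fs = Fm'(1-phiPSII), Fo' = Fm'(1-phiPSII/qP),
    Fo chosen so the Oxborough-Baker estimate returns exactly this Fo',
    and relaxed Fm' = Fm/(1+NPQ-qE).  Deriving parameters from the
    emitted columns therefore recovers the targets to round-off.
    """
    design = design or StageDesign()
    rng = np.random.default_rng(spec.seed + 3)
    plan = spec.physiology_plan
    needed = ("phiPSII", "qP", "NPQ", "qE", "P_N", "g_s", "E", "C_i")
    for k in needed:
        if k not in plan:
            raise ValueError(f"physiology plan lacks parameter {k!r}")
    rows = []
    for si, stage in enumerate(design.physiology_stages):
        draws = {}
        for k in needed:
            means, sd = plan[k]
            draws[k] = means[si] + rng.normal(0.0, sd, spec.n_plants)
        draws["phiPSII"] = draws["phiPSII"].clip(0.01, 0.95)
        draws["qP"] = np.maximum(draws["qP"], draws["phiPSII"] / 0.999)
        draws["NPQ"] = draws["NPQ"].clip(0.01, None)
        draws["qE"] = draws["qE"].clip(0.0, draws["NPQ"])
        fm_prime = fm / (1.0 + draws["NPQ"])
        fs = fm_prime * (1.0 - draws["phiPSII"])
        fo_prime = fm_prime * (1.0 - draws["phiPSII"] / draws["qP"])
        fo = fo_prime / (1.0 + fo_prime * (1.0 / fm - 1.0 / fm_prime))
        fm_relaxed = fm / (1.0 + draws["NPQ"] - draws["qE"])
        for i in range(spec.n_plants):
            rows.append(
                {
                    "plant_id": f"p{i + 1:02d}",
                    "stage": stage,
                    "Fs": fs[i],
                    "Fm_prime": fm_prime[i],
                    "Fo": fo[i],
                    "Fm": fm,
                    "Fm_relaxed": fm_relaxed[i],
                    "PPFD": spec.ppfd,
                    "P_N": draws["P_N"][i],
                    "g_s": max(draws["g_s"][i], 0.0),
                    "E": max(draws["E"][i], 0.0),
                    "C_i": draws["C_i"][i],
                }
            )
    return pd.DataFrame(rows)
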