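"""Run configuration and experimental stage design.

The repeated-dehydration experiment samples maize seedlings at a
well-watered baseline (W), a first 90-min air-drying stress (S1), a
rehydration stage (R1) and a repeated stress (S2).  Transcriptomes were
sequenced at W, S1 and S3 (a third stress), physiology measured at W, S1,
R1 and S2; because selected genes respond alike in S2 and S3 the two
repeated-stress stages are treated as equivalent when transcriptome and
physiology are combined.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["StageDesign", "RunConfig"]


@dataclass(frozen=True)
class StageDesign:
    """Ordered stage labels and the repeated-stress equivalence map.

    Attributes
    ----------
    transcriptome_stages
        Stage labels of the expression samples, in treatment order.
    physiology_stages
        Stage labels of the physiology measurements, in treatment order.
    equivalence_map
        Symmetric mapping identifying stages considered comparable across
        the two data types (by default the repeated stresses S2 and S3).
    """

    transcriptome_stages: tuple[str, ...] = ("W", "S1", "S3")
    physiology_stages: tuple[str, ...] = ("W", "S1", "R1", "S2")
    equivalence_map: dict[str, str] = field(
        default_factory=lambda: {"S2": "S3", "S3": "S2"}
    )

    def __post_init__(self) -> None:
        for a, b in self.equivalence_map.items():
            if self.equivalence_map.get(b) != a:
                raise ValueError(
                    f"equivalence_map is not symmetric: {a!r}->{b!r} "
                    f"but {b!r}->{self.equivalence_map.get(b)!r}"
                )

    def equivalent(self, stage: str) -> str:
        """Return the stage itself or its declared equivalent."""
        return self.equivalence_map.get(stage, stage)

    def shared_stages(self) -> list[tuple[str, str]]:
        """Pairs (transcriptome stage, physiology stage) comparable under the map."""
        pairs = []
        for ts in self.transcriptome_stages:
            for ps in self.physiology_stages:
                if ps == ts or self.equivalent(ps) == ts:
                    pairs.append((ts, ps))
        return pairs


@dataclass
class RunConfig:
    """All thresholds of the analysis, with the published defaults.

    Parameters
    ----------
    q_threshold : float
        FDR cutoff for a differential-expression call (default 0.05).
    lfc_threshold : float
        Minimum |log2 fold change| (default 1.0).
    expr_percentile : float
        Per-sample expression floor: at least one of the two contrasted
        samples must exceed this percentile of that sample's FPKM values
        (default 25).
    variation_min_range : float
        Minimum FPKM range across all samples for a gene to enter the
        co-expression network (default 0.05).
    min_module_size : int
        Smallest allowed co-expression module (default 30).
    metamodule_cut : float
        Eigengene dissimilarity (1 - r) below which modules group into a
        meta-module (default 0.2).
    cut_height : float
        Dissimilarity ceiling for the module tree cut, on the 1 - |r|
        scale.  With six samples the null distribution of |r| between
        unrelated genes is proportional to (1 - r^2), so chance
        correlations are large; the default 0.05 (|r| >= 0.95, chance
        probability ~0.2% per pair) admits only tightly co-expressed
        branches.
    min_mapped_entries : int
        Minimum reference annotation count for a GO term to be tested
        (default 5).
    alpha_phys : float
        Significance level for physiology stage contrasts (default 0.05).
    absorptance : float
        Leaf absorptance used in ETR and phiCO2 (default 0.85).
    psii_fraction : float
        Fraction of absorbed light partitioned to PSII (default 0.5).
    rng_seed : int
        Seed for every stochastic component.
    """

    q_threshold: float = 0.05
    lfc_threshold: float = 1.0
    expr_percentile: float = 25.0
    variation_min_range: float = 0.05
    min_module_size: int = 30
    metamodule_cut: float = 0.2
    cut_height: float = 0.05
    min_mapped_entries: int = 5
    alpha_phys: float = 0.05
    absorptance: float = 0.85
    psii_fraction: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        import math

        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v}")
        if not 0 < self.expr_percentile < 100:
            raise ValueError("expr_percentile must be in (0, 100)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)
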