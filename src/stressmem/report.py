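"""Summary tallies: pattern x category tables and module composition.

Reproduces the style of the published summaries: gene counts per
functional category (rows) by memory pattern (columns) with margins, and
per-module / per-meta-module composition by memory category with
integer percentages (round half away from zero, matching the printed
style; exact fractions are kept in machine output).
"""

from __future__ import annotations

import math

import pandas as pd

from .memory import MEMORY_PATTERNS, PATTERN_CATEGORY
from .network import MetaModuleGrouping, ModulePartition

__all__ = ["tally_patterns", "module_composition", "round_half_away"]

#: column order of the printed pattern tables (the eight responsive patterns)
RESPONSIVE_PATTERNS = ("[+/+]", "[+/-]", "[+/=]", "[=/+]", "[-/-]", "[-/+]", "[-/=]", "[=/-]")

CATEGORIES = ("memory", "delayed-memory", "non-memory", "non-responsive")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def tally_patterns(
    calls: pd.DataFrame, grouping: pd.Series | None = None
) -> pd.DataFrame:
    """Gene counts per group x pattern with row/column/grand margins.

    ``calls`` is a memory-call table indexed by gene with a ``pattern``
    column; ``grouping`` maps gene -> group label (ungrouped genes fall
    into "other").  Derived per-row category counts (memory,
    delayed-memory, non-memory) are appended as extra columns.
    """
    patterns = list(RESPONSIVE_PATTERNS) + ["[=/=]"]
    if grouping is None:
        groups = pd.Series("all", index=calls.index)
    else:
        groups = calls.index.to_series().map(grouping).fillna("other")
    df = pd.DataFrame({"group": groups, "pattern": calls["pattern"]})
    table = (
        df.groupby(["group", "pattern"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=patterns, fill_value=0)
    )
    table["total"] = table[patterns].sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    for cat in ("memory", "delayed-memory", "non-memory"):
        cols = [p for p in patterns if PATTERN_CATEGORY[p] == cat]
        table[cat] = table[cols].sum(axis=1)
    grand = int(table.loc["Total", "total"])
    assert grand == int(table.loc[table.index != "Total", "total"].sum())
    return table


def module_composition(
    calls: pd.DataFrame,
    partition: ModulePartition,
    grouping: MetaModuleGrouping | None = None,
) -> pd.DataFrame:
    """Per-module (and per-meta-module) memory-category composition.

    For every module: size, count and integer percentage of each memory
    category among its genes; meta-module rows aggregate their member
    modules.  Every assigned gene must have a memory call.
    """
    missing = partition.assignment.index.difference(calls.index)
    if len(missing):
        raise ValueError(f"genes lacking a memory call: {list(missing[:5])}")

    def row_for(label, genes) -> dict:
        sub = calls.loc[genes]
        n = len(sub)
        rec: dict = {"unit": label, "size": n}
        for cat in CATEGORIES:
            c = int((sub["category"] == cat).sum())
            rec[f"n_{cat}"] = c
            rec[f"frac_{cat}"] = c / n if n else float("nan")
            rec[f"pct_{cat}"] = round_half_away(100.0 * c / n) if n else 0
        for pat in MEMORY_PATTERNS:
            rec[f"n_{pat}"] = int((sub["pattern"] == pat).sum())
        return rec

    rows = [
        row_for(f"M{m}", partition.genes_in(m)) for m in partition.module_ids
    ]
    if grouping is not None:
        for label, mods in sorted(grouping.members().items()):
            genes = partition.assignment.index[
                partition.assignment.isin(mods)
            ]
            rows.append(row_for(f"meta-{label}", genes))
    out = pd.DataFrame(rows).set_index("unit")

    # conservation: per-category counts over modules match the global tally
    assigned = partition.assignment.index[partition.assignment != 0]
    module_rows = out.loc[[f"M{m}" for m in partition.module_ids]]
    for cat in CATEGORIES:
        total = int((calls.loc[assigned, "category"] == cat).sum())
        assert int(module_rows[f"n_{cat}"].sum()) == total
    return out
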