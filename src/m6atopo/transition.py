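"""m6A topological transitions between two developmental stages.

Genes classified in both stages are cross-tabulated (5 x 5, rows = stage 1,
columns = stage 2).  The overlap ratio of a group is the fraction of its genes
keeping the same label across stages, relative to the group's size in a chosen
reference stage; the transition ratio is the row-normalised table (stage 1 as
reference).  Two derived gene sets track the most dynamic transitions during
development: adult-loss 5MGs (fetal 5MG -> adult NMG) and adult-gain SMGs
(adult SMG not SMG in the fetal stage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import GROUPS, TopologyAssignment

logger = logging.getLogger(__name__)


@dataclass
class TransitionTable:
    counts: pd.DataFrame          # 5x5, rows = stage1 groups, cols = stage2 groups
    shared_genes: list[str]
    stage1_groups: pd.Series      # restricted to shared genes
    stage2_groups: pd.Series
    only_stage1: list[str]
    only_stage2: list[str]

    @property
    def row_marginals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def long_format(self) -> pd.DataFrame:
        """(gene, stage1_group, stage2_group), alluvial-plot ready."""
        return pd.DataFrame({
            "gene_id": self.shared_genes,
            "stage1_group": self.stage1_groups.reindex(self.shared_genes).to_numpy(),
            "stage2_group": self.stage2_groups.reindex(self.shared_genes).to_numpy(),
        })


@dataclass
class TransitionSets:
    adult_loss_5MG: set[str]
    adult_retain_5MG: set[str]
    adult_gain_SMG: set[str]
    adult_retain_SMG: set[str]

    def as_dict(self) -> dict[str, set[str]]:
        return {"adult_loss_5MG": self.adult_loss_5MG,
                "adult_retain_5MG": self.adult_retain_5MG,
                "adult_gain_SMG": self.adult_gain_SMG,
                "adult_retain_SMG": self.adult_retain_SMG}


def cross_tab(a: TopologyAssignment, b: TopologyAssignment) -> TransitionTable:
    """5 x 5 cross-tabulation of group labels over genes classified in both stages."""
    shared = sorted(set(a.groups.index) & set(b.groups.index))
    if not shared:
        raise ValueError("no genes shared between the two assignments")
    g1 = a.groups.reindex(shared)
    g2 = b.groups.reindex(shared)
    counts = pd.crosstab(g1, g2).reindex(index=GROUPS, columns=GROUPS, fill_value=0)
    counts.index.name = "stage1"
    counts.columns.name = "stage2"
    only1 = sorted(set(a.groups.index) - set(b.groups.index))
    only2 = sorted(set(b.groups.index) - set(a.groups.index))
    if only1 or only2:
        logger.info("cross_tab: %d genes only in stage 1, %d only in stage 2",
                    len(only1), len(only2))
    return TransitionTable(counts=counts, shared_genes=shared, stage1_groups=g1,
                           stage2_groups=g2, only_stage1=only1, only_stage2=only2)


def overlap_ratio(t: TransitionTable, group: str, reference: str = "stage1") -> float:
    """Diagonal count of ``group`` over its marginal in the reference stage.

    NaN (undefined) when the reference marginal is zero.
    """
    if reference not in ("stage1", "stage2"):
        raise ValueError("reference must be 'stage1' or 'stage2'")
    marg = (t.row_marginals if reference == "stage1" else t.col_marginals)[group]
    if marg == 0:
        return float("nan")
    return float(t.counts.loc[group, group] / marg)


def overlap_ratios(t: TransitionTable) -> pd.DataFrame:
    """Overlap ratio of every group against both reference stages."""
    return pd.DataFrame({ref: [overlap_ratio(t, g, ref) for g in GROUPS]
                         for ref in ("stage1", "stage2")}, index=pd.Index(GROUPS, name="group"))


def transition_ratio(t: TransitionTable) -> pd.DataFrame:
    """Row-normalised transition table (stage 1 / fetal as reference).

    Rows with a zero marginal are all-NaN.
    """
    marg = t.row_marginals.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = t.counts.to_numpy(dtype=float) / marg[:, None]
    vals[marg == 0] = np.nan
    return pd.DataFrame(vals, index=t.counts.index.copy(), columns=t.counts.columns.copy())


def transition_sets(t: TransitionTable) -> TransitionSets:
    """Derived transition gene sets (stage 1 = fetal, stage 2 = adult)."""
    g1 = t.stage1_groups
    g2 = t.stage2_groups
    return TransitionSets(
        adult_loss_5MG=set(g1.index[(g1 == "5MG") & (g2 == "NMG")]),
        adult_retain_5MG=set(g1.index[(g1 == "5MG") & (g2 == "5MG")]),
        adult_gain_SMG=set(g1.index[(g2 == "SMG") & (g1 != "SMG")]),
        adult_retain_SMG=set(g1.index[(g1 == "SMG") & (g2 == "SMG")]),
    )


def chain_tables(assignments: list[TopologyAssignment]) -> list[TransitionTable]:
    """Pairwise transition tables along a multi-stage chain
    (e.g. hESC -> fetal -> adult)."""
    if len(assignments) < 2:
        raise ValueError("need at least two stages")
    return [cross_tab(a, b) for a, b in zip(assignments, assignments[1:])]
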