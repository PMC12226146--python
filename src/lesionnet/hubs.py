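"""Hubscore computation and cohort-level hub classification.

A node earns one hubscore point per criterion met: top 20% of nodal
strength, top 20% of betweenness centrality, bottom 20% of shortest path
length, bottom 20% of clustering coefficient (score 0..4).  At cohort
level, a node is a *hub* if it scores >= 2 in over half of the reference
(control) subjects, a *nonhub* if it scores 0 in over half, and
*intermediate* otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HubPartition", "hubscore_subject", "classify_cohort", "hub_frequency_table"]

_CRITERIA = {
    "strength": "top",
    "betweenness": "top",
    "path_length": "bottom",
    "clustering": "bottom",
}


@dataclass
class HubPartition:
    """Cohort-level node labels with the supporting control fractions."""

    labels: pd.Series  # "hub" | "nonhub" | "intermediate" per node
    fraction_hubscore_ge2: pd.Series
    fraction_hubscore_0: pd.Series

    @property
    def hubs(self) -> list:
        return list(self.labels[self.labels == "hub"].index)

    @property
    def nonhubs(self) -> list:
        return list(self.labels[self.labels == "nonhub"].index)


def hubscore_subject(
    nodal: pd.DataFrame,
    quantile: float = 0.2,
    return_criteria: bool = False,
):
    """Per-node hubscore for one subject.

    For each criterion the threshold is the linear-interpolation quantile
    of the *defined* values (80th percentile for "top" criteria, 20th for
    "bottom"); a point is awarded for value >= top threshold or <= bottom
    threshold, so ties at the threshold all qualify.  Nodes with an
    undefined metric (floating nodes' path length) are excluded from the
    quantile and earn no point for the path-length and betweenness
    criteria.
    """
    needed = set(_CRITERIA)
    missing = needed - set(nodal.columns)
    if missing:
        raise KeyError(f"nodal table lacks metrics: {sorted(missing)}")

    floating = nodal["path_length"].isna()
    crit = pd.DataFrame(index=nodal.index, dtype=bool)
    for metric, side in _CRITERIA.items():
        vals = nodal[metric]
        defined = vals.notna()
        if metric in ("path_length", "betweenness"):
            defined = defined & ~floating
        v = vals[defined].to_numpy(dtype=float)
        if v.size < 5:
            raise ValueError(
                f"fewer than 5 nodes with defined {metric}: quantile thresholds "
                "are meaningless"
            )
        if np.all(v == v[0]):
            warnings.warn(
                f"all defined values of {metric} are identical; every node "
                "meets the threshold (degenerate quantile)",
                stacklevel=2,
            )
        if side == "top":
            thr = np.quantile(v, 1 - quantile)
            met = (vals >= thr) & defined
        else:
            thr = np.quantile(v, quantile)
            met = (vals <= thr) & defined
        crit[metric] = met.fillna(False)

    score = crit.sum(axis=1).astype(int)
    if return_criteria:
        return score, crit
    return score


def classify_cohort(scores: pd.DataFrame, reference_subjects) -> HubPartition:
    """Label each node hub / nonhub / intermediate from reference subjects.

    ``scores`` is subject x node (hubscores 0..4).  Both classification
    rules use a strict majority (> 0.5) over the reference subjects.
    """
    reference_subjects = list(reference_subjects)
    if not reference_subjects:
        raise ValueError("reference subject list is empty")
    missing = set(reference_subjects) - set(scores.index)
    if missing:
        raise KeyError(f"reference subjects not in score table: {sorted(missing)}")

    ref = scores.loc[reference_subjects]
    frac_ge2 = (ref >= 2).mean(axis=0)
    frac_0 = (ref == 0).mean(axis=0)

    labels = pd.Series("intermediate", index=scores.columns, dtype=object)
    labels[frac_ge2 > 0.5] = "hub"
    labels[(frac_0 > 0.5) & ~(frac_ge2 > 0.5)] = "nonhub"
    return HubPartition(labels=labels, fraction_hubscore_ge2=frac_ge2, fraction_hubscore_0=frac_0)


def hub_frequency_table(scores: pd.DataFrame, groups: pd.Series) -> dict:
    """Per-node 2x2 counts of subject-level hub status (score >= 2) by group.

    Returns ``{node: 2x2 ndarray}`` with rows = the two groups (sorted
    label order) and columns = (hub at subject level, not hub).
    """
    groups = groups.loc[scores.index]
    levels = sorted(groups.unique())
    if len(levels) != 2 or any((groups == g).sum() == 0 for g in levels):
        raise ValueError("exactly two non-empty groups are required")
    tables = {}
    ishub = scores >= 2
    for node in scores.columns:
        rows = []
        for g in levels:
            members = groups == g
            n_hub = int((ishub[node] & members).sum())
            rows.append([n_hub, int(members.sum()) - n_hub])
        tables[node] = np.array(rows)
    return tables
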