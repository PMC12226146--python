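"""Random-graph null normalization of graph metrics.

Observed metrics are scaled by the median of the same metric across an
ensemble of "equivalent" random graphs: graphs on the same nodes whose
upper-triangle weights are a uniform random permutation of the observed
ones (zeros included).  This preserves the node count and the exact
distribution of connectivity values while destroying topology; degree and
strength sequences are *not* preserved.  Medians, not means, are used so
single extreme null draws cannot distort the scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import Connectome
from .metrics import NODAL_METRICS, WHOLEBRAIN_METRICS, compute_all_metrics

__all__ = ["NullNormalization", "random_equivalent_graph", "normalize_metrics"]


def random_equivalent_graph(conn, seed: int = 0) -> Connectome:
    """Uniformly permute the upper-triangle weight multiset.

    The output graph has exactly the same multiset of connectivity values
    (zeros travel with the multiset) placed at uniformly random positions;
    the diagonal stays 0.
    """
    w = conn.weights if isinstance(conn, Connectome) else np.asarray(conn, float)
    n = w.shape[0]
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    vals = rng.permutation(w[iu])
    out = np.zeros_like(w)
    out[iu] = vals
    out = out + out.T
    atlas = conn.atlas if isinstance(conn, Connectome) else None
    return Connectome(weights=out, atlas=atlas)


@dataclass
class NullNormalization:
    """Observed, null-median and normalized metric tables.

    ``nodal_normalized[i, m] = nodal_observed[i, m] / median over the
    ensemble of metric m at node i`` (positional convention); likewise for
    whole-brain metrics.  Entries are NaN where the observed value is
    undefined or the null median is 0; ``n_undefined_null`` counts null
    draws dropped from each median.
    """

    nodal_observed: pd.DataFrame
    nodal_null_median: pd.DataFrame
    nodal_normalized: pd.DataFrame
    wholebrain_observed: dict
    wholebrain_null_median: dict
    wholebrain_normalized: dict
    n_random: int
    seed: int
    n_undefined_null: dict


def normalize_metrics(conn: Connectome, n_random: int = 1000, seed: int = 0) -> NullNormalization:
    """Normalize every metric of ``conn`` against the permutation null.

    Ensemble draw ``k`` uses a seed derived deterministically from
    ``(seed, k)``, so results are reproducible given (conn, n_random,
    seed).  Undefined null values (e.g. assortativity of a degenerate
    draw) are dropped from the median with their count reported.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    nodal_obs, whole_obs = compute_all_metrics(conn)

    root = np.random.SeedSequence(seed)
    draw_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_random)]

    nodal_stack = np.empty((n_random, *nodal_obs.shape))
    whole_stack = {m: np.empty(n_random) for m in WHOLEBRAIN_METRICS}
    for k, dseed in enumerate(draw_seeds):
        null_conn = random_equivalent_graph(conn, seed=dseed)
        nod, who = compute_all_metrics(null_conn)
        nodal_stack[k] = nod[NODAL_METRICS].to_numpy()
        for m in WHOLEBRAIN_METRICS:
            whole_stack[m][k] = who[m]

    with warnings.catch_warnings():
        # all-NaN node/metric slices (e.g. assortativity of degenerate
        # draws) legitimately yield a NaN median, which stays flagged
        warnings.simplefilter("ignore", RuntimeWarning)
        nodal_median = np.nanmedian(nodal_stack, axis=0)
    n_undef = {
        "nodal": int(np.isnan(nodal_stack).sum()),
    }
    nodal_median_df = pd.DataFrame(
        nodal_median, index=nodal_obs.index, columns=NODAL_METRICS
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        norm = nodal_obs[NODAL_METRICS].to_numpy() / np.where(
            nodal_median == 0, np.nan, nodal_median
        )
    nodal_norm_df = pd.DataFrame(norm, index=nodal_obs.index, columns=NODAL_METRICS)

    whole_median: dict = {}
    whole_norm: dict = {}
    for m in WHOLEBRAIN_METRICS:
        vals = whole_stack[m]
        good = vals[~np.isnan(vals)]
        n_undef[m] = int(np.isnan(vals).sum())
        med = float(np.median(good)) if good.size else float("nan")
        whole_median[m] = med
        obs = whole_obs[m]
        if med == 0 or np.isnan(med) or np.isnan(obs):
            whole_norm[m] = float("nan")
        else:
            whole_norm[m] = float(obs / med)

    return NullNormalization(
        nodal_observed=nodal_obs,
        nodal_null_median=nodal_median_df,
        nodal_normalized=nodal_norm_df,
        wholebrain_observed=whole_obs,
        wholebrain_null_median=whole_median,
        wholebrain_normalized=whole_norm,
        n_random=n_random,
        seed=seed,
        n_undefined_null=n_undef,
    )
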