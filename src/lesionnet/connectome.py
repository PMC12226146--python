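"""From ROI time series to a lesion-masked absolute partial-correlation
connectome.

The pipeline stages are: motion scrubbing (framewise displacement, DVARS,
translation limits) -> quality gate -> partial correlations from the
inverse sample covariance -> absolute values -> lesion masking (edges
between majority-lesioned and spared regions zeroed) -> floating-node
detection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.covariance import LedoitWolf

from .atlas import RegionAtlas

__all__ = [
    "ScrubMask",
    "Connectome",
    "QualityGateResult",
    "scrub_mask",
    "quality_gate",
    "partial_correlation_matrix",
    "absolutize",
    "apply_lesion_mask",
    "find_floating_nodes",
    "build_connectome",
    "read_connectome",
    "write_connectome",
]


@dataclass(frozen=True)
class ScrubMask:
    """Per-volume keep/scrub decisions with reasons.

    ``reasons[t]`` is a frozenset drawn from {"fd", "dvars", "translation"},
    empty exactly where ``keep[t]`` is True.
    """

    keep: np.ndarray
    reasons: tuple[frozenset, ...]

    @property
    def n_scrubbed(self) -> int:
        return int((~self.keep).sum())

    @property
    def n_volumes(self) -> int:
        return int(self.keep.size)


@dataclass
class Connectome:
    """Symmetric matrix of absolute partial correlations with provenance.

    Invariants: zero diagonal, symmetry, weights in [0, 1]; every pair in
    ``masked_pairs`` has weight exactly 0; a region is floating iff its row
    sums to 0.
    """

    weights: np.ndarray
    atlas: RegionAtlas | None = None
    masked_pairs: frozenset = frozenset()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            w = w.copy()
            np.fill_diagonal(w, 0.0)
        if w.min() < 0 or w.max() > 1:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def floating_nodes(self) -> frozenset:
        return find_floating_nodes(self)


@dataclass(frozen=True)
class QualityGateResult:
    passed: bool
    scrub_fraction: float
    n_scrubbed: int
    n_volumes: int
    max_scrub_fraction: float


def scrub_mask(
    motion: pd.DataFrame,
    fd_limit: float = 0.5,
    translation_limit: float = 1.5,
    dvars_k: float = 3.0,
) -> ScrubMask:
    """Flag motion-corrupted volumes.

    A volume is scrubbed if FD >= ``fd_limit`` (mm), any |translation| >=
    ``translation_limit`` (mm), or DVARS exceeds its own mean plus
    ``dvars_k`` sample standard deviations.  The FD and translation limits
    are the values the data must stay strictly below to be kept; the DVARS
    rule is adaptive per series.
    """
    if len(motion) < 2:
        raise ValueError("motion table must contain at least 2 volumes")
    fd = motion["fd"].to_numpy(dtype=float)
    dvars = motion["dvars"].to_numpy(dtype=float)
    if fd.min() < 0 or dvars.min() < 0:
        raise ValueError("FD and DVARS must be non-negative")
    trans_cols = [c for c in motion.columns if c.startswith("trans")]
    trans = motion[trans_cols].to_numpy(dtype=float) if trans_cols else np.zeros((len(motion), 0))

    fd_flag = fd >= fd_limit
    trans_flag = (np.abs(trans) >= translation_limit).any(axis=1)
    sd = dvars.std(ddof=1)
    dvars_flag = dvars > dvars.mean() + dvars_k * sd

    keep = ~(fd_flag | trans_flag | dvars_flag)
    reasons = []
    for t in range(len(motion)):
        r = set()
        if fd_flag[t]:
            r.add("fd")
        if dvars_flag[t]:
            r.add("dvars")
        if trans_flag[t]:
            r.add("translation")
        reasons.append(frozenset(r))
    return ScrubMask(keep=keep, reasons=tuple(reasons))


def quality_gate(mask: ScrubMask, max_scrub_fraction: float = 0.2) -> QualityGateResult:
    """Fail a scan when the scrubbed fraction strictly exceeds the cap."""
    frac = mask.n_scrubbed / mask.n_volumes
    return QualityGateResult(
        passed=frac <= max_scrub_fraction,
        scrub_fraction=frac,
        n_scrubbed=mask.n_scrubbed,
        n_volumes=mask.n_volumes,
        max_scrub_fraction=max_scrub_fraction,
    )


def partial_correlation_matrix(
    timeseries: np.ndarray,
    mask: ScrubMask | None = None,
    meta: dict | None = None,
) -> np.ndarray:
    """Full partial-correlation matrix of the (scrubbed) series.

    Each entry r_ij is the correlation between regions i and j after
    removing the linear influence of every other region, obtained by
    standardizing the negative inverse sample covariance:
    ``r_ij = -P_ij / sqrt(P_ii * P_jj)``.  Scrubbed volumes are deleted
    before covariance estimation.  If the sample covariance is numerically
    singular, a Ledoit-Wolf shrinkage estimate is substituted and the
    fallback recorded in ``meta``.
    """
    x = np.asarray(timeseries, dtype=float)
    if mask is not None:
        x = x[mask.keep]
    t, n = x.shape
    if t <= n + 1:
        raise ValueError(
            f"need more than N+1={n + 1} volumes after scrubbing, got {t}"
        )
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"region column {bad} has zero variance")

    cov = np.cov(x, rowvar=False, ddof=1)
    try:
        precision = np.linalg.inv(cov)
        if not np.all(np.isfinite(precision)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        lw = LedoitWolf().fit(x)
        precision = np.linalg.inv(lw.covariance_)
        if meta is not None:
            meta["estimator_fallback"] = "ledoit-wolf shrinkage"

    d = np.sqrt(np.diag(precision))
    pc = -precision / np.outer(d, d)
    pc = (pc + pc.T) / 2
    np.fill_diagonal(pc, 0.0)
    return pc


def absolutize(raw: np.ndarray) -> np.ndarray:
    """Entrywise absolute value (the connectome weight convention)."""
    out = np.abs(np.asarray(raw, dtype=float))
    np.fill_diagonal(out, 0.0)
    return out


def apply_lesion_mask(
    conn: Connectome,
    lesion: np.ndarray,
    threshold: float = 0.5,
) -> Connectome:
    """Zero the edges between majority-lesioned and spared regions.

    A region is "affected" when its lesion-overlap fraction is strictly
    greater than ``threshold``.  Only affected<->unaffected edges are
    zeroed; edges within the affected set and within the spared set are
    untouched.  Idempotent for a fixed lesion vector.
    """
    lesion = np.asarray(lesion, dtype=float)
    n = conn.n_regions
    if lesion.shape != (n,):
        raise ValueError(f"lesion vector must have length {n}")
    if lesion.min() < 0 or lesion.max() > 1:
        raise ValueError("lesion fractions must lie in [0, 1]")

    affected = np.flatnonzero(lesion > threshold)
    weights = conn.weights.copy()
    pairs = set(conn.masked_pairs)
    unaffected = np.setdiff1d(np.arange(n), affected)
    for i in affected:
        weights[i, unaffected] = 0.0
        weights[unaffected, i] = 0.0
        for j in unaffected:
            pairs.add((min(int(i), int(j)), max(int(i), int(j))))
    return Connectome(
        weights=weights,
        atlas=conn.atlas,
        masked_pairs=frozenset(pairs),
        meta={**conn.meta, "lesion_threshold": threshold, "n_affected": int(affected.size)},
    )


def find_floating_nodes(conn: Connectome) -> frozenset:
    """Regions with no remaining connections (all-zero rows)."""
    return frozenset(int(i) for i in np.flatnonzero(conn.weights.sum(axis=1) == 0))


def build_connectome(
    timeseries: np.ndarray,
    motion: pd.DataFrame | None = None,
    lesion: np.ndarray | None = None,
    atlas: RegionAtlas | None = None,
    fd_limit: float = 0.5,
    translation_limit: float = 1.5,
    dvars_k: float = 3.0,
    lesion_threshold: float = 0.5,
    max_scrub_fraction: float = 0.2,
) -> Connectome:
    """Run the full per-subject construction: scrub -> partial correlations
    -> absolute values -> lesion mask.

    Raises if the scan fails the scrubbing quality gate.
    """
    meta: dict = {}
    mask = None
    if motion is not None:
        mask = scrub_mask(motion, fd_limit, translation_limit, dvars_k)
        gate = quality_gate(mask, max_scrub_fraction)
        meta["n_scrubbed"] = mask.n_scrubbed
        meta["scrub_fraction"] = gate.scrub_fraction
        if not gate.passed:
            raise ValueError(
                f"scan failed quality gate: {gate.n_scrubbed}/{gate.n_volumes} "
                f"volumes scrubbed (> {max_scrub_fraction:.0%})"
            )
    pc = partial_correlation_matrix(timeseries, mask, meta)
    conn = Connectome(weights=absolutize(pc), atlas=atlas, meta=meta)
    if lesion is not None:
        conn = apply_lesion_mask(conn, lesion, lesion_threshold)
    return conn


# --------------------------------------------------------------------------
# File formats
# --------------------------------------------------------------------------


def write_connectome(conn: Connectome, path: str | Path) -> None:
    """Write the weight matrix as TSV (region names as header/index) plus a
    sidecar ``*_meta.json``."""
    path = Path(path)
    names = conn.atlas.names if conn.atlas is not None else [
        f"region_{i:03d}" for i in range(conn.n_regions)
    ]
    pd.DataFrame(conn.weights, index=names, columns=names).to_csv(path, sep="\t")
    meta = {
        **conn.meta,
        "masked_pairs": sorted([list(p) for p in conn.masked_pairs]),
        "floating_nodes": sorted(conn.floating_nodes),
    }
    path.with_name(path.stem + "_meta.json").write_text(json.dumps(meta, indent=2))


def read_connectome(path: str | Path, atlas: RegionAtlas | None = None) -> Connectome:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = Path(path).with_name(Path(path).stem + "_meta.json")
    meta: dict = {}
    masked: frozenset = frozenset()
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        masked = frozenset(tuple(p) for p in meta.pop("masked_pairs", []))
        meta.pop("floating_nodes", None)
    return Connectome(weights=df.to_numpy(), atlas=atlas, masked_pairs=masked, meta=meta)
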