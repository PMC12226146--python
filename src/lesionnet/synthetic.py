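"""Synthetic study cohorts with known ground truth.

This module generates everything a resting-state connectome study consumes
-- per-subject ROI time series, motion traces, lesion profiles, demographics
and cognitive scores -- from explicit generative models, so every downstream
stage (partial-correlation estimation, graph metrics, hub classification,
normative w-scores, group statistics) has a recoverable target.

The BOLD-like series are stationary multivariate Gaussian draws whose
covariance is the inverse of a constructed precision matrix; the
partial-correlation estimator applied downstream is then exactly consistent
for the planted network.  Temporal smoothness is emulated with an AR(1)
filter whose stationary covariance equals the target covariance, so the
filter changes the effective number of independent samples but not the
planted structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, make_atlas

__all__ = [
    "GroundTruthNetwork",
    "SyntheticSubject",
    "Cohort",
    "CohortSpec",
    "simulate_ground_truth_network",
    "make_hub_recovery_network",
    "partial_corr_from_precision",
    "sample_timeseries",
    "simulate_motion",
    "simulate_lesion",
    "simulate_cognition",
    "generate_cohort",
    "write_cohort",
    "DEFAULT_TESTS",
    "DEFAULT_DOMAIN_MAP",
    "DEFAULT_TEST_ORIENTATION",
]


class NetworkConstructionError(RuntimeError):
    """Raised when a planted network cannot be made positive definite."""


# --------------------------------------------------------------------------
# Ground-truth networks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A planted partial-correlation network.

    ``partial_corr[i, j] = -precision[i, j] / sqrt(precision[i, i] *
    precision[j, j])`` for i != j; the diagonal is set to 0 and carries no
    meaning.  ``planted_hubs`` are the region ids designed to dominate the
    hub criteria.
    """

    precision: np.ndarray
    partial_corr: np.ndarray
    planted_hubs: frozenset
    seed: int

    @property
    def n_regions(self) -> int:
        return self.precision.shape[0]


def partial_corr_from_precision(precision: np.ndarray) -> np.ndarray:
    """Partial correlations implied by a precision matrix (zero diagonal)."""
    d = np.sqrt(np.diag(precision))
    pc = -precision / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    return pc


def _check_spd(precision: np.ndarray) -> None:
    eigvals = np.linalg.eigvalsh(precision)
    if eigvals.min() <= 0:
        raise NetworkConstructionError(
            f"precision matrix is not positive definite (min eigenvalue "
            f"{eigvals.min():.3e})"
        )


def simulate_ground_truth_network(
    atlas: RegionAtlas,
    n_hubs: int,
    hub_strength_factor: float,
    density: float,
    seed: int,
) -> GroundTruthNetwork:
    """Random sparse network with degree-skewed planted hubs.

    Edges are drawn with Chung-Lu style probabilities proportional to the
    product of node propensities (``hub_strength_factor`` for hubs, 1
    otherwise), targeting an overall edge density of ``density``.  Edge
    magnitudes enter the precision matrix off-diagonal with negative sign,
    and the diagonal is set by strict diagonal dominance, which guarantees
    positive definiteness (Gershgorin); the eigenvalue check is still run
    and a :class:`NetworkConstructionError` raised if it ever fails.
    """
    n = len(atlas)
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    if n_hubs >= n:
        raise ValueError("n_hubs must be smaller than the number of regions")
    if hub_strength_factor <= 1:
        raise ValueError("hub_strength_factor must exceed 1")

    rng = np.random.default_rng(seed)
    hubs = frozenset(rng.choice(n, size=n_hubs, replace=False).tolist())
    prop = np.array([hub_strength_factor if i in hubs else 1.0 for i in range(n)])
    # Scale pairwise propensity products so the expected density matches.
    pij = np.outer(prop, prop).astype(float)
    iu = np.triu_indices(n, k=1)
    pij_u = pij[iu]
    scale = density * len(pij_u) / pij_u.sum()
    probs = np.minimum(1.0, scale * pij_u)

    support = rng.random(len(probs)) < probs
    magnitudes = rng.uniform(0.2, 0.8, size=len(probs)) * support

    precision = np.zeros((n, n))
    precision[iu] = -magnitudes
    precision = precision + precision.T
    row_abs = np.abs(precision).sum(axis=1)
    np.fill_diagonal(precision, 1.05 * row_abs + 0.2)
    _check_spd(precision)

    return GroundTruthNetwork(
        precision=precision,
        partial_corr=partial_corr_from_precision(precision),
        planted_hubs=hubs,
        seed=seed,
    )


def _hub_recovery_template(n: int, n_hubs: int, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Weight template (in partial-correlation units, up to a global scale)
    for exact hub recovery.

    Non-hub nodes are split into structural roles so that each role can
    earn at most one of the four hubscore points (hubscore = top-20%
    strength, top-20% betweenness, bottom-20% path length, bottom-20%
    clustering), while every planted hub earns at least two:

    - ``pair``    : heavy dyads -- high strength, but peripheral (no through
                    traffic, long paths) and triangle-closed (clustering>0).
    - ``bridge``  : sole connector of two leaves -- high betweenness, but
                    modest strength, mid paths, triangle-closed.
    - ``leaf``    : degree-1 nodes -- the only zero-clustering nodes, with
                    the longest paths and lowest strength.
    - ``fastlane``: one strong hub edge -- short paths, but low strength and
                    triangle-closed.
    - ``ring``    : weighted cycle attached to hubs -- mid everything; local
                    ring traffic keeps their betweenness positive but small.

    Weights carry a small multiplicative jitter so quantile thresholds never
    sit on exact ties.
    """
    h = n_hubs
    n_other = n - h
    n_pairnodes = 2 * max(1, h // 2)
    n_bridge = h
    n_leaf = 2 * n_bridge
    n_fast = h
    n_ring = n_other - (n_pairnodes + n_bridge + n_leaf + n_fast)
    if n_ring < 4:
        raise ValueError(
            f"atlas too small for hub-recovery construction: need at least "
            f"{h + n_pairnodes + n_bridge + n_leaf + n_fast + 4} regions for "
            f"{h} hubs, got {n}"
        )

    ids = iter(range(n))
    hubs = [next(ids) for _ in range(h)]
    pairs = [next(ids) for _ in range(n_pairnodes)]
    bridges = [next(ids) for _ in range(n_bridge)]
    leaves = [next(ids) for _ in range(n_leaf)]
    fast = [next(ids) for _ in range(n_fast)]
    ring = [next(ids) for _ in range(n_ring)]

    W = np.zeros((n, n))

    def jitter() -> float:
        return float(rng.uniform(0.97, 1.03))

    def put(i: int, j: int, w: float) -> None:
        w = w * jitter()
        W[i, j] = w
        W[j, i] = w

    # Hub core: interconnected hubs.
    for a in range(h):
        for b in range(a + 1, h):
            put(hubs[a], hubs[b], 0.30)

    # Ring: weighted cycle; each ring node also attaches to two hubs chosen
    # so that cycle neighbours share one hub (closing triangles).
    for k in range(n_ring):
        put(ring[k], ring[(k + 1) % n_ring], 0.26)
    for k in range(n_ring):
        put(ring[k], hubs[k % h], 0.20)
        put(ring[k], hubs[(k + 1) % h], 0.20)

    # Heavy dyads: one dominant edge, plus a weak tether of both partners to
    # the same hub (closing a triangle).
    for p in range(n_pairnodes // 2):
        a, b = pairs[2 * p], pairs[2 * p + 1]
        hub = hubs[p % h]
        put(a, b, 1.30)
        put(a, hub, 0.10)
        put(b, hub, 0.10)

    # Bridges: two hubs (mutually connected, closing a triangle) and two
    # exclusive leaves.
    for k, b in enumerate(bridges):
        put(b, hubs[k % h], 0.16)
        put(b, hubs[(k + 1) % h], 0.16)
        put(b, leaves[2 * k], 0.25)
        put(b, leaves[2 * k + 1], 0.25)

    # Fast lanes: one strong edge into a hub plus a weak second hub edge
    # (hub-hub link closes the triangle).
    for k, f in enumerate(fast):
        put(f, hubs[k % h], 0.80)
        put(f, hubs[(k + 1) % h], 0.08)

    roles = {
        "hubs": hubs,
        "pairs": pairs,
        "bridges": bridges,
        "leaves": leaves,
        "fastlane": fast,
        "ring": ring,
    }
    return W, roles


def make_hub_recovery_network(
    atlas: RegionAtlas,
    n_hubs: int = 8,
    seed: int = 0,
    spectral_margin: float = 0.9,
) -> GroundTruthNetwork:
    """Planted network whose hubs are exactly recoverable by the hubscore.

    The weight template is designed directly in partial-correlation space
    (see :func:`_hub_recovery_template`); the precision matrix is
    ``I - s * W`` with ``s = spectral_margin / lambda_max(W)``, which is
    positive definite and whose implied partial-correlation matrix equals
    ``s * W`` exactly.  The uniform scale ``s`` preserves every ordering the
    quantile-based hub criteria depend on.
    """
    n = len(atlas)
    rng = np.random.default_rng(seed)
    W, roles = _hub_recovery_template(n, n_hubs, rng)

    lam = float(np.linalg.eigvalsh(W).max())
    s = spectral_margin / lam
    precision = np.eye(n) - s * W
    _check_spd(precision)

    return GroundTruthNetwork(
        precision=precision,
        partial_corr=partial_corr_from_precision(precision),
        planted_hubs=frozenset(roles["hubs"]),
        seed=seed,
    )


# --------------------------------------------------------------------------
# Time series, motion, lesions
# --------------------------------------------------------------------------


def sample_timeseries(
    network: GroundTruthNetwork,
    n_volumes: int,
    ar_coefficient: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Draw a T x N BOLD-like series from the planted network.

    Samples are stationary multivariate Gaussian with covariance equal to
    the inverse of the ground-truth precision.  With ``ar_coefficient`` phi
    in [0, 1), consecutive volumes follow ``x_t = phi x_{t-1} +
    sqrt(1 - phi^2) e_t`` with ``e_t ~ N(0, Sigma)``, which leaves the
    stationary covariance (and hence the planted partial correlations)
    unchanged while emulating the temporal smoothness of band-limited BOLD.

    Returns the series together with a metadata dict; if ``n_volumes`` is
    below N + 2 the series is still returned but the metadata carries a
    rank-deficiency warning for downstream estimation.
    """
    if not 0 <= ar_coefficient < 1:
        raise ValueError("ar_coefficient must lie in [0, 1)")
    n = network.n_regions
    meta: dict = {"n_volumes": int(n_volumes), "ar_coefficient": ar_coefficient, "warnings": []}
    if n_volumes < n + 2:
        meta["warnings"].append(
            f"n_volumes={n_volumes} < N+2={n + 2}: downstream covariance may be rank-deficient"
        )

    rng = np.random.default_rng(seed)
    sigma = np.linalg.inv(network.precision)
    chol = np.linalg.cholesky(sigma)
    innov = rng.standard_normal((n_volumes, n)) @ chol.T
    if ar_coefficient == 0:
        return innov, meta

    phi = ar_coefficient
    out = np.empty_like(innov)
    out[0] = innov[0]
    c = np.sqrt(1 - phi**2)
    for t in range(1, n_volumes):
        out[t] = phi * out[t - 1] + c * innov[t]
    return out, meta


def simulate_motion(n_volumes: int, spike_rate: float, seed: int = 0) -> pd.DataFrame:
    """Per-volume motion table (fd, dvars, trans_x/y/z) with spike outliers.

    Baseline framewise displacement sits well below the 0.5 mm scrubbing
    cutoff; at each spike (Bernoulli ``spike_rate`` per volume) FD jumps
    above the cutoff, DVARS jumps far above its mean, and one translation
    axis exceeds the 1.5 mm limit, so the three scrubbing criteria flag the
    same volumes.
    """
    if not 0 <= spike_rate < 1:
        raise ValueError("spike_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    t = int(n_volumes)

    fd = np.clip(np.abs(rng.normal(0.12, 0.05, t)), 0.0, 0.40)
    dvars = np.abs(rng.normal(20.0, 2.0, t))
    trans = rng.normal(0.0, 0.2, (t, 3)).clip(-1.2, 1.2)

    spikes = rng.random(t) < spike_rate
    fd[spikes] = rng.uniform(0.55, 1.3, spikes.sum())
    dvars[spikes] += rng.uniform(40.0, 80.0, spikes.sum())
    axes = rng.integers(0, 3, spikes.sum())
    signs = rng.choice([-1.0, 1.0], spikes.sum())
    trans[np.flatnonzero(spikes), axes] = signs * rng.uniform(1.6, 2.5, spikes.sum())

    return pd.DataFrame(
        {
            "fd": fd,
            "dvars": dvars,
            "trans_x": trans[:, 0],
            "trans_y": trans[:, 1],
            "trans_z": trans[:, 2],
        }
    )


def simulate_lesion(
    atlas: RegionAtlas,
    n_affected: int,
    fractions: Sequence[float],
    seed: int = 0,
) -> np.ndarray:
    """Per-region lesion-overlap fractions for a contiguous unilateral lesion.

    Selects ``n_affected`` regions contiguous by index within one randomly
    chosen hemisphere and assigns them the given fractions; all other
    regions get 0.
    """
    n = len(atlas)
    if n_affected > n:
        raise ValueError("n_affected cannot exceed the number of regions")
    if len(fractions) != n_affected:
        raise ValueError(
            f"fractions has length {len(fractions)}, expected n_affected={n_affected}"
        )
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size and (fractions.min() < 0 or fractions.max() > 1):
        raise ValueError("lesion fractions must lie in [0, 1]")

    out = np.zeros(n)
    if n_affected == 0:
        return out

    rng = np.random.default_rng(seed)
    hemi = rng.choice(["left", "right"])
    hemi_ids = atlas.ids_in_hemisphere(hemi)
    if n_affected > len(hemi_ids):
        raise ValueError(
            f"n_affected={n_affected} exceeds the {len(hemi_ids)} regions of the "
            f"{hemi} hemisphere"
        )
    start = int(rng.integers(0, len(hemi_ids) - n_affected + 1))
    for k in range(n_affected):
        out[hemi_ids[start + k]] = fractions[k]
    return out


# --------------------------------------------------------------------------
# Demographics and cognition
# --------------------------------------------------------------------------

DEFAULT_TESTS = [
    "verbal_fluency",
    "verbal_learning",
    "pegboard",
    "trails_a",
    "digit_span",
    "trails_b",
    "stroop",
    "digit_symbol",
    "matrix_reasoning",
]

DEFAULT_DOMAIN_MAP: dict[str, list[str]] = {
    "language": ["verbal_fluency"],
    "memory": ["verbal_learning"],
    "motor": ["pegboard"],
    "attention": ["trails_a", "digit_span"],
    "executive": ["trails_b", "stroop", "digit_symbol"],
    "proxy_iq": ["matrix_reasoning"],
}

# True means higher raw score = better performance; timed/error scores are
# sign-flipped before normative modelling so that higher w is always better.
DEFAULT_TEST_ORIENTATION: dict[str, bool] = {
    "verbal_fluency": True,
    "verbal_learning": True,
    "pegboard": False,
    "trails_a": False,
    "digit_span": True,
    "trails_b": False,
    "stroop": False,
    "digit_symbol": True,
    "matrix_reasoning": True,
}


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str  # "patient" | "control"
    age: float
    sex: str  # "M" | "F"
    education: int  # Verhage-style ordinal 1..7
    seed: int
    timeseries: np.ndarray | None = None
    timeseries_meta: dict = field(default_factory=dict)
    motion: pd.DataFrame | None = None
    lesion: np.ndarray | None = None
    raw_cognition: dict[str, float] = field(default_factory=dict)


def simulate_cognition(
    subjects: Sequence[SyntheticSubject],
    metrics: pd.DataFrame,
    metric_link: Mapping[str, Mapping[str, float]],
    age_slope: float = -0.3,
    education_slope: float = 2.0,
    noise_sd: float = 5.0,
    intercept: float = 50.0,
    tests: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Raw cognitive scores as linear functions of demographics and metrics.

    ``score = intercept + age_slope*age + education_slope*education +
    sum(coef * metric) + N(0, noise_sd)``, per test.  ``metric_link`` maps
    test name to ``{metric column: coefficient}``; ``metrics`` is a subject
    x metric table aligned with ``subjects``.  Scores are generated on the
    "higher = better" scale and then sign-flipped for tests whose raw
    orientation is timed/error-based, so the stored raw scores behave like
    real instruments.

    Returns the raw-score table and a ground-truth record of every
    coefficient used (for recovery tests).
    """
    if tests is None:
        tests = DEFAULT_TESTS
    rng = np.random.default_rng(seed)
    for test, link in metric_link.items():
        for m in link:
            if m not in metrics.columns:
                raise KeyError(f"metric_link for {test!r} references unknown metric {m!r}")

    rows = []
    for idx, subj in enumerate(subjects):
        row = {}
        for test in tests:
            val = intercept + age_slope * subj.age + education_slope * subj.education
            for m, coef in metric_link.get(test, {}).items():
                val += coef * float(metrics.iloc[idx][m])
            val += rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            if not DEFAULT_TEST_ORIENTATION.get(test, True):
                val = -val
            row[test] = val
        rows.append(row)
    scores = pd.DataFrame(rows, index=[s.subject_id for s in subjects])

    truth = {
        "intercept": intercept,
        "age_slope": age_slope,
        "education_slope": education_slope,
        "noise_sd": noise_sd,
        "metric_link": {t: dict(l) for t, l in metric_link.items()},
    }
    return scores, truth


# --------------------------------------------------------------------------
# Whole-cohort generation
# --------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults mirror the emulated study: 50 patients and 50 individually
    matched controls, a 78-region atlas, 450 volumes per subject, and an
    8-hub planted network.  ``noiseless=True`` bypasses time-series sampling
    and hands each subject the exact ground-truth connectivity (used for
    exact-recovery checks).
    """

    n_patients: int = 50
    n_controls: int = 50
    n_volumes: int = 450
    ar_coefficient: float = 0.3
    spike_rate: float = 0.02
    n_hubs: int = 8
    atlas_args: tuple[int, int, int] = (31, 7, 1)
    lesion_n_affected: int = 4
    lesion_fraction_range: tuple[float, float] = (0.3, 0.95)
    noiseless: bool = False
    cognition_metric_link: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "matrix_reasoning": {"global_clustering": -40.0},
            "trails_b": {"global_clustering": 40.0},
        }
    )
    cognition_noise_sd: float = 5.0
    age_slope: float = -0.3
    education_slope: float = 2.0


@dataclass
class Cohort:
    spec: CohortSpec
    atlas: RegionAtlas
    network: GroundTruthNetwork
    subjects: list[SyntheticSubject]
    cognition_truth: dict
    master_seed: int

    @property
    def participants(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "education": s.education,
            }
            row.update(s.raw_cognition)
            rows.append(row)
        return pd.DataFrame(rows)


def _true_metrics_for_cognition(cohort_subjects, network, atlas) -> pd.DataFrame:
    """Whole-brain metrics of each subject's true (lesion-masked) network.

    Used only by the cognition generator, which needs a per-subject metric
    to link scores to; raw (unnormalized) values are sufficient because the
    link is linear.
    """
    from .connectome import Connectome, apply_lesion_mask
    from .metrics import compute_all_metrics

    rows = []
    for subj in cohort_subjects:
        weights = np.abs(network.partial_corr)
        conn = Connectome(weights=weights, atlas=atlas)
        if subj.lesion is not None and subj.lesion.max() > 0:
            conn = apply_lesion_mask(conn, subj.lesion)
        _, wb = compute_all_metrics(conn)
        rows.append(wb)
    return pd.DataFrame(rows, index=[s.subject_id for s in cohort_subjects])


def generate_cohort(spec: CohortSpec | None = None, master_seed: int = 0) -> Cohort:
    """Generate a full matched patient/control cohort.

    One master seed deterministically derives independent child seeds per
    subject (numpy ``SeedSequence`` spawning), so individual subjects are
    reproducible in isolation.  Controls are matched to patients on sex,
    education, and age (within 3 years), mirroring an individually matched
    design.
    """
    if spec is None:
        spec = CohortSpec()
    atlas = make_atlas(*spec.atlas_args)
    root = np.random.SeedSequence(master_seed)
    net_ss, demo_ss, cog_ss, *subj_ss = root.spawn(3 + spec.n_patients + spec.n_controls)

    net_seed = int(net_ss.generate_state(1)[0] % 2**31)
    network = make_hub_recovery_network(atlas, n_hubs=spec.n_hubs, seed=net_seed)

    demo_rng = np.random.default_rng(demo_ss)
    subjects: list[SyntheticSubject] = []

    patient_demo = []
    for i in range(spec.n_patients):
        patient_demo.append(
            {
                "age": float(demo_rng.uniform(20, 65)),
                "sex": "M" if demo_rng.random() < 0.5 else "F",
                "education": int(demo_rng.integers(1, 8)),
            }
        )

    k = 0
    for i in range(spec.n_patients):
        ss = subj_ss[k]
        k += 1
        seed = int(ss.generate_state(1)[0] % 2**31)
        d = patient_demo[i]
        subjects.append(
            SyntheticSubject(
                subject_id=f"sub-{i + 1:03d}",
                group="patient",
                age=d["age"],
                sex=d["sex"],
                education=d["education"],
                seed=seed,
            )
        )
    for i in range(spec.n_controls):
        ss = subj_ss[k]
        k += 1
        seed = int(ss.generate_state(1)[0] % 2**31)
        d = patient_demo[i % len(patient_demo)]
        age = float(np.clip(d["age"] + demo_rng.uniform(-3, 3), 18, 80))
        subjects.append(
            SyntheticSubject(
                subject_id=f"sub-{spec.n_patients + i + 1:03d}",
                group="control",
                age=age,
                sex=d["sex"],
                education=d["education"],
                seed=seed,
            )
        )

    n = len(atlas)
    for subj in subjects:
        child = np.random.SeedSequence(subj.seed)
        ts_seed, mot_seed, les_seed = (
            int(s.generate_state(1)[0] % 2**31) for s in child.spawn(3)
        )
        if spec.noiseless:
            subj.timeseries = None
            subj.timeseries_meta = {"noiseless": True}
        else:
            subj.timeseries, subj.timeseries_meta = sample_timeseries(
                network, spec.n_volumes, spec.ar_coefficient, seed=ts_seed
            )
        subj.motion = simulate_motion(spec.n_volumes, spec.spike_rate, seed=mot_seed)
        if subj.group == "patient" and spec.lesion_n_affected > 0:
            les_rng = np.random.default_rng(les_seed)
            fractions = les_rng.uniform(
                *spec.lesion_fraction_range, size=spec.lesion_n_affected
            )
            subj.lesion = simulate_lesion(
                atlas, spec.lesion_n_affected, fractions, seed=les_seed
            )
        else:
            subj.lesion = np.zeros(n)

    metrics = _true_metrics_for_cognition(subjects, network, atlas)
    cog_seed = int(cog_ss.generate_state(1)[0] % 2**31)
    scores, truth = simulate_cognition(
        subjects,
        metrics,
        spec.cognition_metric_link,
        age_slope=spec.age_slope,
        education_slope=spec.education_slope,
        noise_sd=spec.cognition_noise_sd,
        seed=cog_seed,
    )
    for subj in subjects:
        subj.raw_cognition = scores.loc[subj.subject_id].to_dict()

    return Cohort(
        spec=spec,
        atlas=atlas,
        network=network,
        subjects=subjects,
        cognition_truth=truth,
        master_seed=master_seed,
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write a cohort directory of TSV tables plus ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = cohort.atlas.names

    cohort.participants.to_csv(outdir / "participants.tsv", sep="\t", index=False)
    for subj in cohort.subjects:
        if subj.timeseries is not None:
            pd.DataFrame(subj.timeseries, columns=names).to_csv(
                outdir / f"{subj.subject_id}_timeseries.tsv", sep="\t", index=False
            )
        subj.motion.to_csv(outdir / f"{subj.subject_id}_motion.tsv", sep="\t", index=False)
        pd.DataFrame({"region": names, "fraction": subj.lesion}).to_csv(
            outdir / f"{subj.subject_id}_lesion.tsv", sep="\t", index=False
        )

    truth = {
        "master_seed": cohort.master_seed,
        "seed_scheme": "numpy SeedSequence(master).spawn per subject, state mod 2**31",
        "network_seed": cohort.network.seed,
        "planted_hubs": sorted(cohort.network.planted_hubs),
        "cognition": cohort.cognition_truth,
        "subject_seeds": {s.subject_id: s.seed for s in cohort.subjects},
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return outdir
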