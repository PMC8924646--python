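"""Synthetic inputs for every pipeline stage.

Two generators:

* :func:`generate_structured_volume` builds GM-like probability volumes in
  which chosen cube nodes share latent 3x3x3 intensity patterns on top of
  i.i.d. Gaussian noise, so the true "connected" cube pairs are known and
  edge-recovery / false-discovery behaviour of the network construction can
  be measured.
* :func:`generate_cohort` builds a prodromal-AD-like cohort: latent
  abnormality flags (network small-world, p-tau, hippocampal volume) are
  drawn first, continuous marker values conditional on the flags, an
  exponential time-to-dementia whose rate scales with per-flag hazard
  ratios (calibrated to a target 2-year progression prevalence), random
  censoring, and longitudinal MMSE / CDR-SB trajectories from a
  random-intercept + random-slope model in which abnormal network topology
  steepens decline.

Both are fully deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .volume_io import GMVolume

__all__ = [
    "VolumeSimSpec",
    "CohortSimSpec",
    "generate_structured_volume",
    "planted_pairs",
    "generate_cohort",
    "measure_edge_fdp",
]


@dataclass(frozen=True)
class VolumeSimSpec:
    """Recipe for a GM-like volume with planted cube-level covariance.

    ``pattern_members`` lists, per latent pattern, the cube-grid coordinates
    (volume voxel index // 3) of the member cubes; if ``None``, ``n_patterns``
    disjoint member sets of size ``members_per_pattern`` are placed at
    seeded random grid positions.  ``target_correlation`` sets the expected
    Pearson correlation between two members of one pattern.
    """

    shape: tuple[int, int, int] = (30, 30, 30)
    n_patterns: int = 8
    members_per_pattern: int = 20
    pattern_members: tuple[tuple[tuple[int, int, int], ...], ...] | None = None
    noise_sd: float = 1.0
    target_correlation: float = 0.9
    smoothing_fwhm_mm: float = 0.0
    voxel_size_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 6 for s in self.shape):
            raise ValueError("each axis must be >= 6 voxels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.target_correlation <= 1):
            raise ValueError("target_correlation must be in (0, 1]")

    @property
    def cube_grid_shape(self) -> tuple[int, int, int]:
        return tuple(s // 3 for s in self.shape)


def _resolve_members(spec: VolumeSimSpec, rng: np.random.Generator):
    """Member cube coordinates per pattern (explicit or seeded random)."""
    grid = spec.cube_grid_shape
    if spec.pattern_members is not None:
        members = [tuple(tuple(c) for c in pat) for pat in spec.pattern_members]
        for pat in members:
            for c in pat:
                if any(not (0 <= c[a] < grid[a]) for a in range(3)):
                    raise ValueError(f"pattern member {c} outside cube grid {grid}")
        return members
    n_cubes = int(np.prod(grid))
    need = spec.n_patterns * spec.members_per_pattern
    if need > n_cubes:
        raise ValueError("more pattern members than cubes in the grid")
    flat = rng.choice(n_cubes, size=need, replace=False)
    coords = np.stack(np.unravel_index(flat, grid), axis=-1)
    return [
        tuple(tuple(int(v) for v in coords[k]) for k in range(i, i + spec.members_per_pattern))
        for i in range(0, need, spec.members_per_pattern)
    ]


def planted_pairs(spec: VolumeSimSpec) -> set[frozenset]:
    """The set of cube-coordinate pairs that share a latent pattern."""
    rng = np.random.default_rng(spec.seed)
    members = _resolve_members(spec, rng)
    pairs: set[frozenset] = set()
    for pat in members:
        for i in range(len(pat)):
            for j in range(i + 1, len(pat)):
                pairs.add(frozenset((pat[i], pat[j])))
    return pairs


def generate_structured_volume(spec: VolumeSimSpec) -> GMVolume:
    """A [0,1] probability volume with planted cube-level covariance.

    The base field is i.i.d. N(0, noise_sd^2).  Each member cube of a
    pattern additionally receives ``s * latent`` with a shared latent
    27-vector and ``s`` chosen so the expected member-member correlation is
    ``target_correlation`` (with ``noise_sd = 0`` members carry the latent
    exactly).  The whole field is then affinely mapped into [0, 1], which
    preserves every Pearson correlation.
    """
    rng = np.random.default_rng(spec.seed)
    members = _resolve_members(spec, rng)
    vol = rng.normal(0.0, spec.noise_sd if spec.noise_sd > 0 else 1.0, size=spec.shape)
    rho = spec.target_correlation
    for pat in members:
        latent = rng.normal(0.0, 1.0, size=(3, 3, 3))
        for (ci, cj, ck) in pat:
            sl = (slice(3 * ci, 3 * ci + 3), slice(3 * cj, 3 * cj + 3), slice(3 * ck, 3 * ck + 3))
            if spec.noise_sd == 0:
                vol[sl] = latent
            else:
                s = spec.noise_sd * np.sqrt(rho / (1.0 - rho)) if rho < 1 else None
                if s is None:
                    vol[sl] = latent
                else:
                    vol[sl] = vol[sl] + s * latent
    if spec.smoothing_fwhm_mm > 0:
        sigma_vox = spec.smoothing_fwhm_mm / (2.354820045 * spec.voxel_size_mm)
        vol = ndimage.gaussian_filter(vol, sigma_vox)
    lo, hi = vol.min(), vol.max()
    data = (vol - lo) / (hi - lo) if hi > lo else np.full_like(vol, 0.5)
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    return GMVolume(data=data, affine=affine, tissue_class="GM")


def measure_edge_fdp(
    spec: VolumeSimSpec,
    spurious_level: float = 0.05,
    n_null: int = 10_000,
    seed: int | None = None,
) -> tuple[float, int]:
    """False-discovery proportion of the thresholded network's edges.

    Runs the full construction pipeline (cube extraction, rotation-maximized
    similarity, permutation threshold, binarization) on a planted-structure
    volume and returns ``(fdp, n_edges)``: the fraction of retained edges
    joining cube pairs that do NOT share a planted pattern, and the edge
    count.  ``seed`` drives the permutation null only; the volume comes from
    ``spec.seed``.
    """
    from .network_construction import (
        build_network,
        build_similarity_matrix,
        extract_cubes,
        permutation_threshold,
    )

    vol = generate_structured_volume(spec)
    nodes = extract_cubes(vol)
    sim = build_similarity_matrix(nodes)
    thr = permutation_threshold(nodes, sim, spurious_level, n_null, seed=seed)
    net = build_network(sim, thr)
    truth = planted_pairs(spec)
    coords = [tuple(c) for c in nodes.grid_coords]
    edges = np.argwhere(np.triu(net.adjacency, k=1))
    if len(edges) == 0:
        return 0.0, 0
    spurious = sum(1 for i, j in edges if frozenset((coords[i], coords[j])) not in truth)
    return spurious / len(edges), int(len(edges))


#: Marker distributions conditional on the driving abnormality flag:
#: (normal mean, normal sd, abnormal mean, abnormal sd), on the scales the
#: clinic reports (network metrics unitless, p-tau pg/ml, volumes ml).
DEFAULT_MARKER_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "gamma": (1.72, 0.09, 1.55, 0.09),
    "lambda_": (1.12, 0.03, 1.09, 0.03),
    "sigma": (1.55, 0.08, 1.40, 0.08),
    "ptau_pg_ml": (40.0, 12.0, 75.0, 20.0),
    "hv_norm_ml": (4.2, 0.5, 3.3, 0.4),
}


@dataclass(frozen=True)
class CohortSimSpec:
    """Recipe for a prodromal-AD cohort with known ground truth.

    Abnormality flags for the network small-world metric, CSF p-tau and
    hippocampal volume are independent Bernoulli draws; each abnormal flag
    multiplies the exponential progression rate by its hazard ratio, and the
    baseline rate is calibrated so the expected 2-year progression
    prevalence hits ``target_prevalence_2y`` (34% by default).  Cognitive
    trajectories follow a random-slope model in which an abnormal network
    flag steepens decline.
    """

    n_subjects: int = 250
    flag_prevalence: dict = field(
        default_factory=lambda: {"sigma": 0.5, "ptau": 0.5, "hv": 0.5}
    )
    hazard_ratios: dict = field(
        default_factory=lambda: {"sigma": 2.0, "ptau": 2.0, "hv": 2.0}
    )
    marker_params: dict = field(default_factory=lambda: dict(DEFAULT_MARKER_PARAMS))
    target_prevalence_2y: float = 0.34
    horizon_years: float = 2.0
    max_follow_up_years: float = 4.0
    censoring_rate: float = 0.10
    visit_times: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    mmse_baseline: float = 27.0
    mmse_slopes: tuple[float, float] = (-0.4, -1.4)  # (normal, abnormal network)
    cdr_sb_baseline: float = 1.5
    cdr_sb_slopes: tuple[float, float] = (0.5, 1.1)
    sigma_b2: float = 0.1
    sigma_e2: float = 1.0
    intercept_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.target_prevalence_2y < 1):
            raise ValueError("target prevalence must lie in (0, 1)")
        if any(h <= 0 for h in self.hazard_ratios.values()):
            raise ValueError("hazard ratios must be positive")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")


def _calibrate_base_rate(spec: CohortSimSpec) -> float:
    """Baseline hazard hitting the target observed 2-year prevalence.

    The target is the fraction of subjects with an *observed* progression
    event within the horizon (the number a cohort table reports), so random
    censoring competing with the event is folded into the expectation:
    with event rate lam and censoring rate c, P(observed event by h) =
    lam/(lam+c) * (1 - exp(-(lam+c) h)).
    """
    keys = ("sigma", "ptau", "hv")
    prev = [spec.flag_prevalence[k] for k in keys]
    hrs = [spec.hazard_ratios[k] for k in keys]
    h = min(spec.horizon_years, spec.max_follow_up_years)
    c = spec.censoring_rate

    def expected_prev(rate: float) -> float:
        total = 0.0
        for bits in range(8):
            w = 1.0
            mult = 1.0
            for k in range(3):
                on = (bits >> k) & 1
                w *= prev[k] if on else 1 - prev[k]
                if on:
                    mult *= hrs[k]
            lam = rate * mult
            total += w * lam / (lam + c) * (1.0 - np.exp(-(lam + c) * h))
        return total

    target = spec.target_prevalence_2y
    try:
        return float(optimize.brentq(lambda r: expected_prev(r) - target, 1e-10, 50.0))
    except ValueError as err:
        raise ValueError(
            f"target 2-year prevalence {target} unattainable with hazard ratios "
            f"{spec.hazard_ratios} (expected prevalence ranges over "
            f"({expected_prev(1e-10):.4f}, {expected_prev(50.0):.4f}))"
        ) from err


def generate_cohort(spec: CohortSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and its longitudinal visits.

    Returns ``(cohort, visits)``: one row per subject with marker values,
    censored ``time_years``/``event``, covariates and the ground-truth
    ``true_*`` flags; and a long-format table of (subject_id, visit_years,
    mmse, cdr_sb).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    flags = {
        k: rng.random(n) < spec.flag_prevalence[k] for k in ("sigma", "ptau", "hv")
    }

    # continuous markers conditional on the driving flag; the three network
    # metrics all follow the network (sigma) flag
    markers: dict[str, np.ndarray] = {}
    driver = {"gamma": "sigma", "lambda_": "sigma", "sigma": "sigma",
              "ptau_pg_ml": "ptau", "hv_norm_ml": "hv"}
    for name, (m0, s0, m1, s1) in spec.marker_params.items():
        f = flags[driver[name]]
        markers[name] = np.where(f, rng.normal(m1, s1, n), rng.normal(m0, s0, n))
    # prodromal AD: everyone amyloid-abnormal (below the 813 pg/ml clinical cut)
    markers["abeta42_pg_ml"] = rng.normal(600.0, 120.0, n)

    base_rate = _calibrate_base_rate(spec)
    mult = np.ones(n)
    for k in ("sigma", "ptau", "hv"):
        mult *= np.where(flags[k], spec.hazard_ratios[k], 1.0)
    t_event = rng.exponential(1.0 / (base_rate * mult))
    if spec.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censoring_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, spec.max_follow_up_years)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    cohort = pd.DataFrame(
        {
            "subject_id": [f"s{i:04d}" for i in range(n)],
            **markers,
            "time_years": np.maximum(time, 1e-6),
            "event": event,
            "age_years": rng.normal(70.0, 7.0, n).round(1),
            "sex": rng.choice(["F", "M"], n),
            "education_years": rng.integers(6, 21, n),
            "scanner_id": rng.choice(["scanner_a", "scanner_b", "scanner_c"], n),
            "true_sigma_abnormal": flags["sigma"].astype(int),
            "true_ptau_abnormal": flags["ptau"].astype(int),
            "true_hv_abnormal": flags["hv"].astype(int),
        }
    )

    t = np.asarray(spec.visit_times)
    net = flags["sigma"]
    rows = []
    for score, baseline, slopes in (
        ("mmse", spec.mmse_baseline, spec.mmse_slopes),
        ("cdr_sb", spec.cdr_sb_baseline, spec.cdr_sb_slopes),
    ):
        mean_slope = np.where(net, slopes[1], slopes[0])
        b0 = rng.normal(0.0, spec.intercept_sd, n)
        b1 = rng.normal(0.0, np.sqrt(spec.sigma_b2), n)
        eps = rng.normal(0.0, np.sqrt(spec.sigma_e2), (n, t.size))
        y = baseline + b0[:, None] + (mean_slope + b1)[:, None] * t[None, :] + eps
        rows.append(y)
    mmse, cdr = rows
    visits = pd.DataFrame(
        {
            "subject_id": np.repeat(cohort["subject_id"].to_numpy(), t.size),
            "visit_years": np.tile(t, n),
            "mmse": mmse.reshape(-1),
            "cdr_sb": cdr.reshape(-1),
        }
    )
    return cohort, visits
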