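"""Synthetic organ-level PET cohorts with controlled covariance structure.

Scans are drawn from group-specific multivariate normal distributions over
organ SUV_90-120 values.  A cohort is defined by a normative interorgan
correlation structure shared by control (vehicle) groups, with three kinds of
planted manipulation available for test groups:

* edge-specific correlation deltas (endotoxin-challenge-like rewiring of
  specific organ links),
* organ-specific mean elevation (inflammation-driven tracer uptake),
* global signal suppression plus a flattened uptake profile (dose-dependent
  pharmacologic blocking of the specific binding component).

Optionally each scan also carries full synthetic time-activity curves whose
90-120 min average reproduces the drawn SUV exactly, so the SUV
quantification stage can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .suv import ScanRecord

DEFAULT_ORGANS: tuple[str, ...] = (
    "brain",
    "heart",
    "lungs",
    "kidneys",
    "adrenal_glands",
    "spleen",
    "liver",
    "vena_cava",
)

#: Typical organ SUV_90-120 for a TSPO tracer in healthy mice (heart, kidneys
#: and liver high; brain and blood pool low).
NORMAL_MEAN_SUV: tuple[float, ...] = (0.4, 2.5, 1.2, 2.8, 2.0, 1.5, 2.2, 0.5)

#: Uptake profile under near-complete blocking of specific binding: high-TSPO
#: organs collapse toward free-tracer levels while excretory organs (kidneys,
#: liver) and the blood pool retain relatively more signal.
BLOCKED_MEAN_SUV: tuple[float, ...] = (0.35, 0.7, 0.55, 1.3, 0.6, 0.45, 1.5, 1.1)

VEHICLE_GROUPS: tuple[str, ...] = (
    "Vehicles 2 h",
    "Vehicles 24 h",
    "Vehicles 7 d",
    "Vehicles B",
)


def normative_correlation(
    organs: tuple[str, ...] = DEFAULT_ORGANS,
    base: float = 0.6,
    vena_cava: float = 0.2,
) -> np.ndarray:
    """Normative interorgan correlation: ``base`` everywhere except blood-pool
    (vena cava) links, which couple only weakly to parenchymal organs."""
    k = len(organs)
    r = np.full((k, k), base)
    np.fill_diagonal(r, 1.0)
    if "vena_cava" in organs:
        i = organs.index("vena_cava")
        r[i, :] = vena_cava
        r[:, i] = vena_cava
        r[i, i] = 1.0
    return r


def covariance_from_correlation(corr: np.ndarray, sd: np.ndarray) -> np.ndarray:
    sd = np.asarray(sd, dtype=float)
    return corr * np.outer(sd, sd)


def nearest_psd_correlation(corr: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Repair a symmetric matrix to the nearest PSD correlation matrix by
    eigenvalue clipping at ``eig_floor``, then rescaling to unit diagonal."""
    corr = 0.5 * (corr + corr.T)
    w, v = np.linalg.eigh(corr)
    if w.min() >= eig_floor:
        return corr
    w = np.clip(w, eig_floor, None)
    fixed = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    return 0.5 * (fixed + fixed.T)


@dataclass
class TACModel:
    """Mono-exponential washout to a plateau, used to synthesize TACs whose
    90-120 min average equals the drawn SUV exactly.

    The normalized shape is ``s(t) = p + (1 - p) * exp(-k t)`` with plateau
    fraction ``p`` and washout rate ``k`` (1/min); the curve is rescaled per
    organ so its duration-weighted average over the SUV window matches the
    target value.
    """

    washout_rate: float = 0.03
    plateau_fraction: float = 0.6
    frame_edges: tuple[float, ...] = tuple(float(t) for t in range(0, 121, 10))

    def frame_means(self) -> np.ndarray:
        """Analytic frame averages of the normalized shape."""
        e = np.asarray(self.frame_edges)
        a, b = e[:-1], e[1:]
        k, p = self.washout_rate, self.plateau_fraction
        return p + (1 - p) * (np.exp(-k * a) - np.exp(-k * b)) / (k * (b - a))


@dataclass
class GroupSpec:
    """Sampling distribution for one experimental group."""

    label: str
    n_scans: int
    mean_suv: np.ndarray
    covariance: np.ndarray
    edge_perturbations: list[tuple[str, str, float]] = field(default_factory=list)
    global_scale: float = 1.0
    tac_model: TACModel | None = None
    cohort: str = "1"

    def __post_init__(self) -> None:
        self.mean_suv = np.asarray(self.mean_suv, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.n_scans < 1:
            raise ValueError(f"{self.label}: n_scans must be >= 1")
        if self.covariance.shape != (self.mean_suv.size, self.mean_suv.size):
            raise ValueError(f"{self.label}: covariance shape mismatch")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError(f"{self.label}: covariance not symmetric")
        if np.linalg.eigvalsh(self.covariance).min() < -1e-8:
            raise ValueError(f"{self.label}: covariance not PSD")
        if not self.global_scale > 0:
            raise ValueError(f"{self.label}: global_scale must be > 0")


@dataclass
class CohortConfig:
    """Full cohort description: organ panel, groups and RNG seed."""

    organs: tuple[str, ...] = DEFAULT_ORGANS
    groups: list[GroupSpec] = field(default_factory=list)
    n_ref_target: int = 15
    seed: int = 0
    reference_labels: tuple[str, ...] = VEHICLE_GROUPS

    def __post_init__(self) -> None:
        if len(self.organs) == 0 or len(set(self.organs)) != len(self.organs):
            raise ValueError("organ list must be non-empty with unique names")
        if self.n_ref_target < 3:
            raise ValueError("n_ref_target must be >= 3")
        for g in self.groups:
            if g.mean_suv.size != len(self.organs):
                raise ValueError(f"{g.label}: mean_suv length != organ count")


def _apply_edge_perturbations(
    covariance: np.ndarray,
    organs: tuple[str, ...],
    perturbations: list[tuple[str, str, float]],
    repair_tol: float = 0.05,
    max_iterations: int = 500,
) -> np.ndarray:
    """Add correlation deltas on named edges and repair to a PSD correlation.

    Repair alternates projections between the PSD cone (eigenvalue clipping)
    and the affine constraint fixing the requested edges and the unit
    diagonal, so requested values are honoured exactly whenever the
    constrained matrix is PSD-representable.  Raises if the achievable value
    still differs from a requested edge by more than ``repair_tol``.
    """
    sd = np.sqrt(np.diag(covariance))
    corr = covariance / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    targets: dict[tuple[int, int], float] = {}
    for a, b, delta in perturbations:
        i, j = organs.index(a), organs.index(b)
        if i == j:
            raise ValueError(f"cannot perturb diagonal edge {a}-{b}")
        new = corr[i, j] + delta
        if not -1.0 <= new <= 1.0:
            raise ValueError(f"perturbed correlation {new:.3f} on {a}-{b} outside [-1, 1]")
        corr[i, j] = corr[j, i] = new
        targets[(min(i, j), max(i, j))] = new
    x = corr.copy()
    for _ in range(max_iterations):
        y = nearest_psd_correlation(x)
        x = y.copy()
        for (i, j), want in targets.items():
            x[i, j] = x[j, i] = want
        np.fill_diagonal(x, 1.0)
        if np.abs(x - y).max() < 1e-10:
            break
    fixed = nearest_psd_correlation(x)
    offending = [
        f"{organs[i]}-{organs[j]} (requested {want:.3f}, got {fixed[i, j]:.3f})"
        for (i, j), want in targets.items()
        if abs(fixed[i, j] - want) > repair_tol
    ]
    if offending:
        raise ValueError("PSD repair could not honour edges: " + "; ".join(offending))
    return covariance_from_correlation(fixed, sd)


def _synthesize_tacs(
    suv: np.ndarray,
    organs: tuple[str, ...],
    model: TACModel,
    dose_mbq: float,
    weight_g: float,
    window: tuple[float, float] = (90.0, 120.0),
) -> dict[str, np.ndarray]:
    edges = np.asarray(model.frame_edges)
    shape = model.frame_means()
    mid = 0.5 * (edges[:-1] + edges[1:])
    dur = edges[1:] - edges[:-1]
    in_win = (mid >= window[0]) & (mid <= window[1])
    shape_win = np.sum(shape[in_win] * dur[in_win]) / np.sum(dur[in_win])
    tacs = {}
    for idx, organ in enumerate(organs):
        suv_frames = shape * (suv[idx] / shape_win)
        conc = suv_frames * dose_mbq * 1000.0 / weight_g   # back to kBq/mL
        tacs[organ] = np.column_stack([edges[:-1], edges[1:], conc])
    return tacs


def simulate_cohort(config: CohortConfig, with_tacs: bool | None = None) -> list[ScanRecord]:
    """Draw a full cohort of scans.

    One RNG stream is seeded from ``config.seed`` and advanced group by group
    in declaration order, so output is reproducible and unaffected by what
    downstream code does with it.  Each scan's SUV vector is drawn from the
    group's multivariate normal (mean scaled by ``global_scale``, SDs scaled
    likewise so the coefficient of variation is preserved, edge perturbations
    applied on the correlation scale).  When TACs are requested they are
    synthesized so their windowed average equals the drawn SUV.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ScanRecord] = []
    for g in config.groups:
        cov = g.covariance
        if g.edge_perturbations:
            cov = _apply_edge_perturbations(cov, config.organs, g.edge_perturbations)
        cov = cov * g.global_scale**2
        mean = g.mean_suv * g.global_scale
        doses = np.clip(rng.normal(10.0, 3.4, size=g.n_scans), 2.0, None)
        weights = np.clip(rng.normal(29.2, 3.4, size=g.n_scans), 15.0, None)
        draws = rng.multivariate_normal(mean, cov, size=g.n_scans)
        slug = g.label.replace(" ", "-")
        make_tacs = g.tac_model is not None if with_tacs is None else with_tacs
        for k in range(g.n_scans):
            tacs = None
            if make_tacs:
                model = g.tac_model or TACModel()
                tacs = _synthesize_tacs(draws[k], config.organs, model, doses[k], weights[k])
            records.append(
                ScanRecord(
                    scan_id=f"{slug}-{k + 1:02d}",
                    group=g.label,
                    cohort=g.cohort,
                    injected_dose=float(doses[k]),
                    weight=float(weights[k]),
                    tacs=tacs,
                    suv_90_120=pd.Series(draws[k], index=list(config.organs)),
                )
            )
    return records


def _default_sd(mean: np.ndarray, cv: float = 0.15) -> np.ndarray:
    return cv * np.asarray(mean)


def default_group(
    label: str,
    n_scans: int,
    organs: tuple[str, ...] = DEFAULT_ORGANS,
    mean_suv: np.ndarray | None = None,
    corr: np.ndarray | None = None,
    cv: float = 0.15,
    **kwargs,
) -> GroupSpec:
    """Group with the normative correlation structure and 15% CV noise."""
    mean = np.asarray(NORMAL_MEAN_SUV if mean_suv is None else mean_suv, dtype=float)
    r = normative_correlation(organs) if corr is None else corr
    return GroupSpec(
        label=label,
        n_scans=n_scans,
        mean_suv=mean,
        covariance=covariance_from_correlation(r, _default_sd(mean, cv)),
        **kwargs,
    )


def lps_blocking_config(seed: int, with_tacs: bool = False) -> CohortConfig:
    """Study design emulating the two-cohort LPS + pharmacologic-blocking
    experiment: 50 scans in 12 groups over 8 organs.

    Cohort L (post-QC sizes): Vehicles 2 h/24 h/7 d (3/5/4) and LPS 2 h/24 h/
    7 d (6/6/7).  The 2 h endotoxin response elevates brain, heart and kidney
    uptake and decorrelates the brain-heart-kidneys links; the 24 h response
    shifts to liver, spleen and heart; by 7 d the network has recovered.

    Cohort B: Vehicles B (3), Baseline (3) and four blocking doses (6/1/3/3)
    with increasing occupancy: means blend toward the blocked uptake profile,
    interorgan correlations weaken, and the global scale drops dose-
    dependently.
    """
    organs = DEFAULT_ORGANS
    normal = np.asarray(NORMAL_MEAN_SUV)
    blocked = np.asarray(BLOCKED_MEAN_SUV)

    def lps_mean(mult: dict[str, float]) -> np.ndarray:
        m = normal.copy()
        for organ, f in mult.items():
            m[organs.index(organ)] *= f
        return m

    def blocked_group(label, n, occupancy, gscale):
        mean = (1 - occupancy) * normal + occupancy * blocked
        corr = normative_correlation(organs, base=0.6 * (1 - occupancy) + 0.3 * occupancy)
        return default_group(
            label, n, organs, mean_suv=mean, corr=corr,
            global_scale=gscale, cohort="B",
            tac_model=TACModel() if with_tacs else None,
        )

    tac = TACModel() if with_tacs else None
    groups = [
        default_group("Vehicles 2 h", 3, organs, cohort="L", tac_model=tac),
        default_group("Vehicles 24 h", 5, organs, cohort="L", tac_model=tac),
        default_group("Vehicles 7 d", 4, organs, cohort="L", tac_model=tac),
        default_group(
            "LPS 2 h", 6, organs,
            mean_suv=lps_mean({"brain": 1.8, "heart": 1.5, "kidneys": 1.5}),
            edge_perturbations=[
                ("brain", "heart", -0.5),
                ("brain", "kidneys", -0.5),
                ("heart", "kidneys", -0.5),
            ],
            cohort="L", tac_model=tac,
        ),
        default_group(
            "LPS 24 h", 6, organs,
            mean_suv=lps_mean({"liver": 2.8, "spleen": 3.2, "heart": 1.5}),
            edge_perturbations=[
                ("liver", "spleen", -0.5),
                ("liver", "heart", -0.5),
                ("spleen", "heart", -0.5),
            ],
            cohort="L", tac_model=tac,
        ),
        default_group("LPS 7 d", 7, organs, cohort="L", tac_model=tac),
        default_group("Vehicles B", 3, organs, cohort="B", tac_model=tac),
        default_group("Baseline", 3, organs, cohort="B", tac_model=tac),
        blocked_group("Dose 1", 6, occupancy=0.15, gscale=0.9),
        blocked_group("Dose 2", 1, occupancy=0.25, gscale=0.8),
        blocked_group("Dose 3", 3, occupancy=0.88, gscale=0.45),
        blocked_group("Dose 4", 3, occupancy=0.96, gscale=0.30),
    ]
    return CohortConfig(organs=organs, groups=groups, n_ref_target=15, seed=seed)


def lps_blocking_cohort(seed: int, with_tacs: bool = False) -> list[ScanRecord]:
    """Simulate the 50-scan, 12-group LPS + blocking study design."""
    return simulate_cohort(lps_blocking_config(seed, with_tacs=with_tacs))


def null_vehicle_config(
    seed: int,
    group_sizes: dict[str, int] | None = None,
    organs: tuple[str, ...] = DEFAULT_ORGANS,
) -> CohortConfig:
    """Vehicles-only null cohort (default 15 scans in the four vehicle
    subgroups, 3/5/4/3) sharing the normative covariance, for calibration of
    the leave-one-out deviation analysis."""
    sizes = group_sizes or {"Vehicles 2 h": 3, "Vehicles 24 h": 5, "Vehicles 7 d": 4, "Vehicles B": 3}
    groups = [
        default_group(label, n, organs, cohort="B" if label == "Vehicles B" else "L")
        for label, n in sizes.items()
    ]
    return CohortConfig(
        organs=organs, groups=groups, n_ref_target=sum(sizes.values()), seed=seed
    )
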