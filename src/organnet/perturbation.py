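"""Single-scan perturbation analysis of the interorgan covariance network.

The normative (reference, REF) network is the organ x organ Pearson
correlation of SUV_90-120 across the control scans.  For each target scan a
perturbed network (PER) is recomputed after adding the scan to the reference
group; control scans themselves use a leave-one-out variant where the scan is
removed instead.  The differential network DIFF = PER - REF is normalized
edge-wise to z-scores, yielding one deviation matrix per scan.

The default normalization follows the individual differential covariance
convention for a one-scan perturbation of a Pearson correlation,

    z_ij = (r_PER,ij - r_REF,ij) / s_ij,   s_ij = (1 - r_REF,ij^2) / (n_REF - 1),

with an alternative empirical mode that standardizes each edge's delta
against the leave-one-out delta distribution of the reference pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .suv import SUVTable

log = logging.getLogger(__name__)

#: Cap applied to z on degenerate edges (|r_REF| = 1 with nonzero delta).
Z_CAP_DEFAULT = 50.0


@dataclass
class CovarianceNetwork:
    """Organ x organ Pearson correlation matrix with its sample size."""

    organs: list[str]
    r: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.organs)
        if self.r.shape != (k, k):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix not symmetric")
        if self.n < 3:
            raise ValueError("need n >= 3 scans")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.organs, columns=self.organs)


@dataclass
class DeviationMatrix:
    """One scan's edge-wise deviation from the normative network."""

    scan_id: str
    organs: list[str]
    delta_r: np.ndarray
    z: np.ndarray
    n_ref: int
    loo_flag: bool

    def z_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.organs, columns=self.organs)

    def upper_z(self) -> np.ndarray:
        """Unique off-diagonal z values (upper triangle, row-major)."""
        iu = np.triu_indices(len(self.organs), k=1)
        return self.z[iu]


def _pearson_matrix(values: np.ndarray, organs: list[str]) -> np.ndarray:
    sd = values.std(axis=0)
    if np.any(sd == 0):
        bad = [organs[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance organ(s) across scans: {bad}")
    r = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return np.clip(0.5 * (r + r.T), -1.0, 1.0)


def reference_covariance(table: SUVTable, reference_labels: set[str]) -> CovarianceNetwork:
    """REF: Pearson correlation over all scans carrying a reference label."""
    mask = table.groups.isin(reference_labels).to_numpy()
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"need >= 3 reference scans, found {n}")
    values = table.values[mask]
    return CovarianceNetwork(table.organs, _pearson_matrix(values, table.organs), n)


def perturbed_covariance(
    ref_table: SUVTable,
    target: pd.Series,
    mode: str,
) -> CovarianceNetwork:
    """PER: recompute the correlation with the target scan added to
    (``add_one``) or removed from (``leave_one_out``) the reference set.

    ``ref_table`` must contain only reference scans; ``target`` is the scan's
    organ SUV vector named with its scan id.
    """
    scan_id = target.name
    in_ref = scan_id in ref_table.data.index
    if mode == "add_one":
        if in_ref:
            raise ValueError(f"add_one target {scan_id!r} is already in the reference set")
        values = np.vstack([ref_table.values, target.reindex(ref_table.organs).to_numpy()])
    elif mode == "leave_one_out":
        if not in_ref:
            raise ValueError(f"leave_one_out target {scan_id!r} is not in the reference set")
        keep = ref_table.data.index != scan_id
        values = ref_table.values[keep]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CovarianceNetwork(ref_table.organs, _pearson_matrix(values, ref_table.organs), len(values))


def deviation_zscores(
    ref: CovarianceNetwork,
    per: CovarianceNetwork,
    scan_id: str,
    loo_flag: bool = False,
    z_cap: float = Z_CAP_DEFAULT,
    edge_scale: np.ndarray | None = None,
) -> DeviationMatrix:
    """DIFF = PER - REF, normalized edge-wise to z-scores.

    ``edge_scale`` overrides the analytic scale ``(1 - r_REF^2)/(n_REF - 1)``
    (used by the empirical normalization mode).  Degenerate edges with zero
    scale map to z = 0 when the delta is zero, else to ``sign(delta) * z_cap``.
    """
    if ref.organs != per.organs:
        raise ValueError("organ ordering differs between REF and PER")
    delta = per.r - ref.r
    s = edge_scale if edge_scale is not None else (1.0 - ref.r**2) / (ref.n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(s > 0, delta / np.where(s > 0, s, 1.0), np.sign(delta) * z_cap)
    np.fill_diagonal(z, 0.0)
    np.fill_diagonal(delta, 0.0)
    return DeviationMatrix(scan_id, list(ref.organs), delta, z, ref.n, loo_flag)


def _loo_deltas(ref_table: SUVTable, ref: CovarianceNetwork) -> dict[str, np.ndarray]:
    out = {}
    for scan_id in ref_table.scan_ids:
        per = perturbed_covariance(ref_table, ref_table.data.loc[scan_id], "leave_one_out")
        out[scan_id] = per.r - ref.r
    return out


def all_deviations(
    table: SUVTable,
    reference_labels: set[str],
    z_mode: str = "analytic",
    z_cap: float = Z_CAP_DEFAULT,
) -> list[DeviationMatrix]:
    """One deviation matrix per scan: leave-one-out for reference scans,
    add-one for everything else.

    ``z_mode='analytic'`` uses the (1 - r^2)/(n - 1) scale; ``'empirical'``
    standardizes each edge against the SD of the reference pool's own
    leave-one-out deltas.
    """
    if z_mode not in ("analytic", "empirical"):
        raise ValueError(f"unknown z_mode {z_mode!r}")
    ref = reference_covariance(table, reference_labels)
    ref_ids = [s for s in table.scan_ids if table.groups[s] in reference_labels]
    ref_table = table.subset(ref_ids)

    edge_scale = None
    loo = None
    if z_mode == "empirical":
        loo = _loo_deltas(ref_table, ref)
        stack = np.stack(list(loo.values()))
        edge_scale = stack.std(axis=0, ddof=1)
        np.fill_diagonal(edge_scale, 1.0)

    out = []
    n_loo = 0
    for scan_id in table.scan_ids:
        is_ref = table.groups[scan_id] in reference_labels
        per = perturbed_covariance(
            ref_table, table.data.loc[scan_id], "leave_one_out" if is_ref else "add_one"
        )
        out.append(
            deviation_zscores(ref, per, scan_id, loo_flag=is_ref, z_cap=z_cap, edge_scale=edge_scale)
        )
        n_loo += is_ref
    log.info(
        "deviation matrices: %d scans (%d leave-one-out, %d add-one), n_ref=%d",
        len(out), n_loo, len(out) - n_loo, ref.n,
    )
    return out


def deviations_long_table(deviations: list[DeviationMatrix], ref: CovarianceNetwork) -> pd.DataFrame:
    """Long-format edge table: one row per scan x unique organ pair."""
    iu, ju = np.triu_indices(len(ref.organs), k=1)
    rows = []
    for dev in deviations:
        for i, j in zip(iu, ju):
            rows.append(
                {
                    "scan_id": dev.scan_id,
                    "organ_i": ref.organs[i],
                    "organ_j": ref.organs[j],
                    "r_ref": ref.r[i, j],
                    "r_per": ref.r[i, j] + dev.delta_r[i, j],
                    "delta_r": dev.delta_r[i, j],
                    "z": dev.z[i, j],
                }
            )
    return pd.DataFrame(rows)
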