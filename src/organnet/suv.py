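"""Organ-level SUV quantification from PET time-activity curves.

The static measure feeding every network stage is SUV averaged over the
90-120 min post-injection window (``SUV_90-120``).  Tissue activity
concentration (kBq/mL) is normalized by injected dose per body weight,
giving the dimensionless g/mL SUV convention standard in preclinical PET.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Averaging window (minutes post-injection) for the static uptake measure.
SUV_WINDOW: tuple[float, float] = (90.0, 120.0)


def _validate_tac(organ: str, tac: np.ndarray) -> np.ndarray:
    tac = np.asarray(tac, dtype=float)
    if tac.ndim != 2 or tac.shape[1] != 3:
        raise ValueError(f"TAC for {organ!r} must be (n_frames, 3): start, end, value")
    order = np.argsort(tac[:, 0])
    tac = tac[order]
    if np.any(tac[:, 0] >= tac[:, 1]):
        raise ValueError(f"TAC for {organ!r} has frames with start >= end")
    if np.any(tac[1:, 0] < tac[:-1, 1] - 1e-9):
        raise ValueError(f"TAC for {organ!r} has overlapping frames")
    return tac


@dataclass
class ScanRecord:
    """One scan: metadata plus organ TACs and/or static SUV values.

    Parameters
    ----------
    scan_id, group, cohort
        Identifiers; ``group`` is the experimental group label used by all
        downstream group-level statistics.
    injected_dose
        Injected activity in MBq (must be positive).
    weight
        Animal body weight in g (must be positive).
    tacs
        Optional mapping organ -> ``(n_frames, 3)`` array of
        ``(start_min, end_min, activity_kBq_per_mL)`` rows.  Frames must be
        non-overlapping with ``start < end``.
    suv_90_120
        Optional precomputed per-organ static SUV, indexed by organ name.
    """

    scan_id: str
    group: str
    cohort: str
    injected_dose: float
    weight: float
    tacs: dict[str, np.ndarray] | None = None
    suv_90_120: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.injected_dose > 0:
            raise ValueError(f"{self.scan_id}: injected_dose must be > 0")
        if not self.weight > 0:
            raise ValueError(f"{self.scan_id}: weight must be > 0")
        if self.tacs is not None:
            self.tacs = {o: _validate_tac(o, t) for o, t in self.tacs.items()}
        if self.suv_90_120 is not None:
            self.suv_90_120 = pd.Series(self.suv_90_120, dtype=float)
            if self.suv_90_120.index.has_duplicates:
                raise ValueError(f"{self.scan_id}: duplicate organ names")

    @property
    def organs(self) -> list[str]:
        if self.suv_90_120 is not None:
            return list(self.suv_90_120.index)
        if self.tacs is not None:
            return list(self.tacs)
        return []


@dataclass
class SUVTable:
    """Scans x organs matrix of SUV_90-120 with per-scan group labels."""

    data: pd.DataFrame          # index scan_id, columns organs
    groups: pd.Series           # index scan_id -> group label

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy()).all():
            bad = self.data.stack()
            bad = bad[~np.isfinite(bad)]
            raise ValueError(f"non-finite SUV values at {list(bad.index[:5])}")
        if list(self.groups.index) != list(self.data.index):
            raise ValueError("groups index must match the scan order of data")

    @property
    def scan_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def organs(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset(self, scan_ids: list[str]) -> "SUVTable":
        return SUVTable(self.data.loc[scan_ids], self.groups.loc[scan_ids])


def tac_to_suv(tac: np.ndarray, injected_dose: float, weight: float) -> np.ndarray:
    """Normalize a time-activity curve to SUV units.

    SUV = concentration (kBq/mL) x weight (g) / dose (kBq); frame timing is
    unchanged.  ``injected_dose`` is in MBq and converted internally.
    """
    if not injected_dose > 0:
        raise ValueError("injected_dose must be > 0")
    if not weight > 0:
        raise ValueError("weight must be > 0")
    tac = _validate_tac("<tac>", np.asarray(tac, dtype=float))
    out = tac.copy()
    out[:, 2] = tac[:, 2] * weight / (injected_dose * 1000.0)
    return out


def suv_90_120(
    suv_tac: np.ndarray,
    window: tuple[float, float] = SUV_WINDOW,
    weighted: bool = True,
) -> float:
    """Average SUV over frames whose midpoints fall in ``window`` (inclusive).

    Frames are weighted by duration by default; set ``weighted=False`` for a
    plain mean over qualifying frames.
    """
    tac = _validate_tac("<tac>", np.asarray(suv_tac, dtype=float))
    mid = 0.5 * (tac[:, 0] + tac[:, 1])
    lo, hi = window
    mask = (mid >= lo) & (mid <= hi)
    if not mask.any():
        raise ValueError(
            f"no frame midpoint in [{lo}, {hi}] min; "
            f"frames span [{tac[:, 0].min()}, {tac[:, 1].max()}] min"
        )
    sel = tac[mask]
    w = (sel[:, 1] - sel[:, 0]) if weighted else np.ones(len(sel))
    return float(np.sum(w * sel[:, 2]) / np.sum(w))


def build_suv_table(
    records: list[ScanRecord],
    window: tuple[float, float] = SUV_WINDOW,
    weighted: bool = True,
) -> SUVTable:
    """Assemble the scans x organs SUV_90-120 matrix.

    Precomputed ``suv_90_120`` vectors pass through unchanged; otherwise the
    static SUV is computed from each record's TACs.  Scan and organ orderings
    follow the input.  All records must share the same organ set.
    """
    if not records:
        raise ValueError("no records")
    organs = records[0].organs
    rows = []
    for rec in records:
        if rec.organs and sorted(rec.organs) != sorted(organs):
            extra = set(rec.organs) ^ set(organs)
            raise ValueError(f"{rec.scan_id}: organ set differs from first record: {sorted(extra)}")
        if rec.suv_90_120 is not None:
            vec = rec.suv_90_120.reindex(organs)
        elif rec.tacs is not None:
            vec = pd.Series(
                {
                    o: suv_90_120(
                        tac_to_suv(rec.tacs[o], rec.injected_dose, rec.weight),
                        window=window,
                        weighted=weighted,
                    )
                    for o in organs
                }
            ).reindex(organs)
        else:
            raise ValueError(f"{rec.scan_id}: neither TACs nor SUV values present")
        if not np.isfinite(vec.to_numpy()).all():
            bad = [o for o, v in vec.items() if not np.isfinite(v)]
            raise ValueError(f"{rec.scan_id}: non-finite SUV for organs {bad}")
        rows.append(vec)
        log.debug("QC %s: SUV min %.3g max %.3g", rec.scan_id, vec.min(), vec.max())
    data = pd.DataFrame(rows, index=[r.scan_id for r in records])
    groups = pd.Series({r.scan_id: r.group for r in records}).loc[data.index]
    log.info(
        "SUV table: %d scans x %d organs, SUV range [%.3g, %.3g]",
        *data.shape, data.to_numpy().min(), data.to_numpy().max(),
    )
    return SUVTable(data, groups)
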