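"""Next-best greedy optimization of electrode configurations.

Choosing K non-colliding electrodes to maximize ROI coverage is a
set-cover-type problem without optimal substructure; exhaustive search
is intractable beyond two or three electrodes.  The next-best search
adds, at every step, the candidate trajectory that maximally decreases
the cost (number of unrecordable ROI patches) at the *primary*
discernibility threshold, breaking ties by the cost decrease at the
secondary and tertiary thresholds and finally by a seeded random draw.
Candidates colliding with any selected electrode are masked permanently.
Because the search is iterative, the optimized configuration of any
prefix size X is simply the first X electrodes.

The same machinery orders a fixed (e.g. clinically implanted) electrode
set "in the best possible order", classifies electrodes as inside an
ROI, and evaluates configurations transferred between heads by a rigid
transform.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .forward import ConductivityModel, build_lead_field, sources_from_cortex
from .geometry import DistanceIndex, SurfaceMesh
from .patch_sources import PatchLeadField, build_patch_lead_field, grow_patches
from .sensitivity import ROI, RSReport, THRESHOLDS_UV, recordable_matrix

__all__ = [
    "PriorityOrder",
    "Configuration",
    "contact_rows_for",
    "next_best_search",
    "rs_curves",
    "best_order",
    "electrode_in_roi",
    "transfer_configuration",
    "TransferResult",
    "exhaustive_best",
]


@dataclass(frozen=True)
class PriorityOrder:
    """Permutation of the discernibility thresholds (uV), most important
    first."""

    thresholds: tuple[float, float, float] = (500.0, 200.0, 1000.0)

    def __post_init__(self):
        if sorted(self.thresholds) != sorted(THRESHOLDS_UV):
            raise ValueError(
                f"priority must permute {THRESHOLDS_UV}, got {self.thresholds}")

    @classmethod
    def parse(cls, text: str) -> "PriorityOrder":
        vals = tuple(float(v) for v in text.split(","))
        return cls(vals)  # type: ignore[arg-type]


@dataclass
class Configuration:
    """Ordered electrode selection with per-step costs at every threshold."""

    trajectory_ids: list[int]
    costs_by_threshold: dict[float, list[int]]   # thr -> cost after each step
    priority: PriorityOrder
    seed: int | None = None
    rs_report: RSReport | None = None
    tie_breaks: int = 0

    def __len__(self) -> int:
        return len(self.trajectory_ids)

    def to_json_dict(self) -> dict:
        d = {
            "trajectory_ids": [int(i) for i in self.trajectory_ids],
            "priority_uV": list(self.priority.thresholds),
            "costs_by_threshold": {
                str(int(t)): [int(c) for c in cs]
                for t, cs in self.costs_by_threshold.items()},
            "seed": self.seed,
            "tie_breaks": int(self.tie_breaks),
        }
        if self.rs_report is not None:
            d["rs_report"] = self.rs_report.to_json_dict()
        return d


def contact_rows_for(n_trajectories: int, n_contacts: int = 16) -> list[np.ndarray]:
    """Row indices of each trajectory's contacts under the stacked-contact
    convention: trajectory i owns rows [i*n_contacts, (i+1)*n_contacts)."""
    return [np.arange(i * n_contacts, (i + 1) * n_contacts)
            for i in range(n_trajectories)]


def _roi_recordable(patch_lf: PatchLeadField, electrodes: list[np.ndarray],
                    roi: ROI) -> dict[float, np.ndarray]:
    """Per-threshold (n_electrodes, n_roi_patches) recordability."""
    mask = roi.mask(patch_lf.patch_centers)
    if not mask.any():
        raise ValueError("ROI contains no patch centres")
    out = {}
    for thr in THRESHOLDS_UV:
        r = recordable_matrix(patch_lf, electrodes, thr)
        out[thr] = r[:, mask]
    return out


def _greedy(recordable: dict[float, np.ndarray], collision: np.ndarray | None,
            priority: PriorityOrder, max_electrodes: int,
            seed: int | None, candidates: np.ndarray,
            require_gain: bool) -> Configuration:
    """Shared greedy loop for selection (require_gain) and ordering."""
    rng = np.random.default_rng(seed)
    p1, p2, p3 = priority.thresholds
    n_elec = recordable[p1].shape[0]
    p_total = recordable[p1].shape[1]
    available = np.zeros(n_elec, dtype=bool)
    available[candidates] = True
    covered = {t: np.zeros(p_total, dtype=bool) for t in THRESHOLDS_UV}
    chosen: list[int] = []
    costs: dict[float, list[int]] = {t: [] for t in THRESHOLDS_UV}
    ties = 0

    while available.any() and len(chosen) < max_electrodes:
        avail_idx = np.flatnonzero(available)
        gain1 = (recordable[p1][avail_idx] & ~covered[p1]).sum(axis=1)
        best = gain1.max()
        if require_gain and best == 0:
            break
        cand = avail_idx[gain1 == best]
        if len(cand) > 1:
            gain2 = (recordable[p2][cand] & ~covered[p2]).sum(axis=1)
            cand = cand[gain2 == gain2.max()]
        if len(cand) > 1:
            gain3 = (recordable[p3][cand] & ~covered[p3]).sum(axis=1)
            cand = cand[gain3 == gain3.max()]
        if len(cand) > 1:
            ties += 1
            pick = int(rng.choice(cand))
        else:
            pick = int(cand[0])
        chosen.append(pick)
        available[pick] = False
        if collision is not None:
            available &= ~collision[pick]
        for t in THRESHOLDS_UV:
            covered[t] |= recordable[t][pick]
            costs[t].append(p_total - int(covered[t].sum()))

    return Configuration(trajectory_ids=chosen, costs_by_threshold=costs,
                         priority=priority, seed=seed, tie_breaks=ties)


def next_best_search(patch_lf: PatchLeadField, electrodes: list[np.ndarray],
                     collision: np.ndarray | None, roi: ROI,
                     priority: PriorityOrder | None = None,
                     max_electrodes: int = 31,
                     seed: int | None = None) -> Configuration:
    """Greedy next-best selection from all candidate electrodes.

    ``electrodes`` maps each candidate trajectory to its contact rows in
    the patch lead field (see :func:`contact_rows_for`); ``collision``
    is the candidate-pairwise collision matrix (or None to allow all
    pairs).  Stops after ``max_electrodes`` or when no remaining
    candidate improves the cost at the primary threshold.
    """
    if not electrodes:
        raise ValueError("candidate electrode set is empty")
    priority = priority or PriorityOrder()
    rec = _roi_recordable(patch_lf, electrodes, roi)
    config = _greedy(rec, collision, priority, max_electrodes, seed,
                     np.arange(len(electrodes)), require_gain=True)
    config.rs_report = _report_from(rec, config)
    return config


def best_order(patch_lf: PatchLeadField, electrodes: list[np.ndarray],
               member_ids: np.ndarray, roi: ROI,
               priority: PriorityOrder | None = None,
               seed: int | None = None) -> Configuration:
    """Order a fixed electrode set (e.g. the clinically implanted one) so
    each addition decreases the cost maximally; no selection occurs, all
    members are placed."""
    member_ids = np.asarray(member_ids, dtype=np.int64)
    if member_ids.size == 0:
        raise ValueError("electrode set is empty")
    priority = priority or PriorityOrder()
    rec = _roi_recordable(patch_lf, electrodes, roi)
    config = _greedy(rec, None, priority, len(member_ids), seed,
                     member_ids, require_gain=False)
    config.rs_report = _report_from(rec, config)
    return config


def _report_from(rec: dict[float, np.ndarray],
                 config: Configuration) -> RSReport:
    p_total = rec[THRESHOLDS_UV[0]].shape[1]
    rs_by_count: dict[float, list[float]] = {}
    p_i: dict[float, int] = {}
    for thr in THRESHOLDS_UV:
        covered = np.zeros(p_total, dtype=bool)
        curve = []
        for e in config.trajectory_ids:
            covered |= rec[thr][e]
            curve.append(100.0 * covered.sum() / p_total)
        rs_by_count[thr] = curve
        p_i[thr] = int(covered.sum())
    default_thr = config.priority.thresholds[0]
    strength = np.zeros(p_total, dtype=int)
    for e in config.trajectory_ids:
        strength += rec[default_thr][e].astype(int)
    return RSReport(thresholds=THRESHOLDS_UV, rs_by_count=rs_by_count,
                    recording_strength=strength, p_total=p_total, p_i=p_i)


def rs_curves(patch_lf: PatchLeadField, electrodes: list[np.ndarray],
              config: Configuration, roi: ROI) -> RSReport:
    """RS at every prefix length of a configuration, all three thresholds."""
    rec = _roi_recordable(patch_lf, electrodes, roi)
    return _report_from(rec, config)


def exhaustive_best(recordable: np.ndarray, collision: np.ndarray | None,
                    k: int) -> tuple[tuple[int, ...], int]:
    """Exhaustively best non-colliding k-subset by covered-patch count.

    Only feasible for small candidate sets; used as the optimality
    reference the greedy search is compared against.
    """
    n = recordable.shape[0]
    best_cover, best_set = -1, ()
    for combo in itertools.combinations(range(n), k):
        if collision is not None and any(
                collision[a, b] for a, b in itertools.combinations(combo, 2)):
            continue
        cover = int(np.any(recordable[list(combo)], axis=0).sum())
        if cover > best_cover:
            best_cover, best_set = cover, combo
    return best_set, recordable.shape[1] - best_cover


# ---------------------------------------------------------------------------
# Electrode-in-ROI rule and configuration transfer
# ---------------------------------------------------------------------------

def electrode_in_roi(contact_points: np.ndarray, roi_index: DistanceIndex,
                     near_mm: float = 3.0, far_mm: float = 100.0) -> bool:
    """An electrode belongs to an ROI iff at least one contact is within
    ``near_mm`` of the ROI surface and at least half of its contacts are
    within ``far_mm``."""
    d = roi_index.min_distance(np.asarray(contact_points, dtype=float))
    half = int(np.ceil(len(d) / 2))
    return bool(d.min() <= near_mm and (d <= far_mm).sum() >= half)


@dataclass
class TransferResult:
    """Outcome of moving an optimized configuration onto another head."""

    n_at_75: int
    rs_matched: float
    rs_transferred: float
    percent_reduction: float
    electrode_valid: np.ndarray      # per electrode, 2.5 mm sulci rule
    configuration_valid: bool
    reached_75: bool


def _check_rigid(rotation: np.ndarray, translation: np.ndarray) -> None:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-8):
        raise ValueError("transform must be orthonormal (no scaling/shear)")
    if np.linalg.det(rotation) < 0:
        raise ValueError("transform must not reflect (det must be +1)")


def transfer_configuration(matched_rs_curve: list[float],
                           contact_points: np.ndarray,
                           rotation: np.ndarray, translation: np.ndarray,
                           target_cortex: SurfaceMesh,
                           roi: ROI,
                           target_sulci: SurfaceMesh | None = None,
                           conductivity: ConductivityModel | None = None,
                           patch_area_cm2: float = 10.0,
                           moment_density: float = 0.465,
                           thr: float = 500.0,
                           rs_floor: float = 75.0,
                           sulci_invalid_mm: float = 2.5) -> TransferResult:
    """Evaluate a configuration transferred to another head by a rigid
    (6-DOF) transform.

    The matched case's RS-vs-count curve (at the threshold of interest)
    fixes the electrode count: the minimum number reaching
    ``rs_floor`` percent RS (the full set, flagged, if never reached).
    Contacts are mapped into the target space and the lead field is
    recomputed there with the target head's forward model.  Electrodes
    passing within ``sulci_invalid_mm`` of the target sulci make the
    configuration invalid, but all electrodes are kept in the RS
    estimate (best-case sensitivity).
    """
    _check_rigid(rotation, translation)
    contact_points = np.asarray(contact_points, dtype=float)
    if contact_points.ndim != 3:
        raise ValueError("contact_points must be (n_electrodes, n_contacts, 3)")

    curve = np.asarray(matched_rs_curve, dtype=float)
    reached = curve >= rs_floor
    if reached.any():
        n_at = int(np.flatnonzero(reached)[0]) + 1
        reached_75 = True
    else:
        n_at = len(curve)
        reached_75 = False
    rs_matched = float(curve[n_at - 1])

    used = contact_points[:n_at]
    moved = used @ np.asarray(rotation, dtype=float).T \
        + np.asarray(translation, dtype=float)

    conductivity = conductivity or ConductivityModel()
    sources = sources_from_cortex(target_cortex)
    flat = moved.reshape(-1, 3)
    lf = build_lead_field(sources, flat, conductivity)
    patches = grow_patches(target_cortex, patch_area_cm2)
    patch_lf = build_patch_lead_field(lf, patches, moment_density,
                                      target_cortex)
    n_contacts = moved.shape[1]
    electrodes = contact_rows_for(n_at, n_contacts)

    from .sensitivity import recording_sensitivity
    rs_transferred = recording_sensitivity(patch_lf, electrodes, roi, thr)

    if rs_matched > 0:
        reduction = 100.0 * (rs_matched - rs_transferred) / rs_matched
    else:
        reduction = float("nan")

    if target_sulci is not None and target_sulci.n_faces > 0:
        idx = DistanceIndex(target_sulci)
        valid = np.array([idx.min_distance(e).min() >= sulci_invalid_mm
                          for e in moved])
    else:
        valid = np.ones(n_at, dtype=bool)

    return TransferResult(n_at_75=n_at, rs_matched=rs_matched,
                          rs_transferred=rs_transferred,
                          percent_reduction=reduction,
                          electrode_valid=valid,
                          configuration_valid=bool(valid.all()),
                          reached_75=reached_75)
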