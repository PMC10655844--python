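"""Recording-sensitivity metric, cost function and recording-radius
estimation.

A patch source is *recordable by an electrode* when its voltage magnitude
reaches the discernibility threshold at a minimum of two contacts of
that electrode — source localization needs multiple contacts seeing the
same event.  For a configuration of electrodes and a region of interest
(ROI), the recording sensitivity is

    RS_{i,thr}(ROI) = 100 * P_{i,thr}(ROI) / P_total(ROI)   [percent]

where P_{i,thr} counts ROI patches recordable by at least one electrode
of configuration i at threshold thr, and P_total counts all patches with
centre elements in the ROI (one patch per cortical element).  The cost
minimized by the trajectory optimizer is the complement

    C_{i,thr}(ROI) = P_total(ROI) - P_{i,thr}(ROI).

Discernibility thresholds of 200, 500 and 1000 uV bracket clinical
interictal-spike amplitudes: 200 uV is four standard deviations of
typical background noise (a Gaussian's +/-4 SD span covers 99.99% of
samples), ~500 uV is the 25th percentile of clinician-marked spike
maxima, and ~1000 uV is their mean.  The trace statistics that justify
those thresholds (common-average referencing, noise SD, spike maxima)
are implemented here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .patch_sources import PatchLeadField

__all__ = [
    "THRESHOLDS_UV",
    "ROI",
    "RSReport",
    "SEEGTrace",
    "RadiusEstimate",
    "recordable_by_electrode",
    "recordable_matrix",
    "recording_strength",
    "recording_sensitivity",
    "cost",
    "estimate_recording_radius",
    "contact_sampling",
    "common_average_reference",
    "noise_threshold",
    "spike_amplitude_stats",
]

THRESHOLDS_UV = (200.0, 500.0, 1000.0)
MIN_CONTACTS_PER_ELECTRODE = 2


@dataclass(frozen=True)
class ROI:
    """A region of interest: set of cortex triangle (element) indices."""

    element_ids: frozenset[int]
    name: str = "ROI"

    def __post_init__(self):
        if not self.element_ids:
            raise ValueError("ROI must be non-empty")

    @classmethod
    def from_ids(cls, ids, name: str = "ROI") -> "ROI":
        return cls(frozenset(int(i) for i in ids), name)

    def mask(self, patch_centers: np.ndarray) -> np.ndarray:
        """Boolean mask of patches whose centre element is in the ROI."""
        ids = np.fromiter(self.element_ids, dtype=np.int64)
        return np.isin(patch_centers, ids)


@dataclass
class RSReport:
    """Per-threshold RS curves and final coverage for a configuration."""

    thresholds: tuple[float, ...]
    rs_by_count: dict[float, list[float]]   # thr -> RS% after 1..n electrodes
    recording_strength: np.ndarray          # electrodes-per-patch, default thr
    p_total: int
    p_i: dict[float, int]                   # thr -> recordable count, full set

    def to_json_dict(self) -> dict:
        return {
            "thresholds_uV": list(self.thresholds),
            "rs_by_count": {str(int(t)): [float(v) for v in c]
                            for t, c in self.rs_by_count.items()},
            "recording_strength": [int(v) for v in self.recording_strength],
            "P_total": int(self.p_total),
            "P_i": {str(int(t)): int(v) for t, v in self.p_i.items()},
        }


@dataclass
class SEEGTrace:
    """Multichannel voltage trace in microvolts."""

    voltages: np.ndarray          # (channels, samples) uV
    sample_rate: float
    spike_free_mask: np.ndarray   # (samples,) bool

    def __post_init__(self):
        self.voltages = np.atleast_2d(np.asarray(self.voltages, dtype=float))
        if not np.isfinite(self.voltages).all():
            raise ValueError("trace contains non-finite values")
        self.spike_free_mask = np.asarray(self.spike_free_mask, dtype=bool)


# ---------------------------------------------------------------------------
# Recordability and the RS metric
# ---------------------------------------------------------------------------

def recordable_by_electrode(patch_lf: PatchLeadField,
                            electrode_contact_rows: np.ndarray,
                            thr: float) -> np.ndarray:
    """Per-patch recordability by a single electrode.

    |V| >= thr is binarized per contact and patch, summed over the
    electrode's contacts, and compared against the two-contact minimum.
    The threshold comparison is inclusive.
    """
    rows = np.asarray(electrode_contact_rows, dtype=np.int64)
    if rows.size == 0 or rows.size > 16:
        raise ValueError("an electrode has 1-16 contact rows")
    if rows.min() < 0 or rows.max() >= patch_lf.matrix.shape[0]:
        raise ValueError("contact row index out of range")
    hits = (np.abs(patch_lf.matrix[rows]) >= thr).sum(axis=0)
    return hits >= MIN_CONTACTS_PER_ELECTRODE


def recordable_matrix(patch_lf: PatchLeadField,
                      electrodes: list[np.ndarray],
                      thr: float) -> np.ndarray:
    """(n_electrodes, n_patches) recordability, one row per electrode."""
    if not electrodes:
        return np.zeros((0, patch_lf.n_patches), dtype=bool)
    return np.stack([recordable_by_electrode(patch_lf, rows, thr)
                     for rows in electrodes])


def recording_strength(patch_lf: PatchLeadField,
                       electrodes: list[np.ndarray],
                       thr: float) -> np.ndarray:
    """Number of electrodes able to record each patch."""
    return recordable_matrix(patch_lf, electrodes, thr).sum(axis=0)


def recording_sensitivity(patch_lf: PatchLeadField,
                          electrodes: list[np.ndarray],
                          roi: ROI, thr: float) -> float:
    """RS in percent: share of ROI patches recordable by the configuration."""
    mask = roi.mask(patch_lf.patch_centers)
    p_total = int(mask.sum())
    if p_total == 0:
        raise ValueError("ROI contains no patch centres")
    if not electrodes:
        return 0.0
    covered = recordable_matrix(patch_lf, electrodes, thr).any(axis=0)
    p_i = int((covered & mask).sum())
    return 100.0 * p_i / p_total


def cost(patch_lf: PatchLeadField, electrodes: list[np.ndarray],
         roi: ROI, thr: float) -> int:
    """Number of ROI patches *not* recordable: C = P_total - P_i."""
    mask = roi.mask(patch_lf.patch_centers)
    p_total = int(mask.sum())
    if p_total == 0:
        raise ValueError("ROI contains no patch centres")
    if not electrodes:
        return p_total
    covered = recordable_matrix(patch_lf, electrodes, thr).any(axis=0)
    return p_total - int((covered & mask).sum())


# ---------------------------------------------------------------------------
# Recording radius
# ---------------------------------------------------------------------------

@dataclass
class RadiusEstimate:
    """Recording radius with its per-bin median-RS profile."""

    radius_cm: float
    any_bin_passed: bool
    bin_edges_cm: np.ndarray      # right edges of occupied bins
    median_rs: np.ndarray         # median over contacts, per bin
    rs_floor: float
    thr: float


def estimate_recording_radius(patch_lf: PatchLeadField,
                              sample_contact_rows: np.ndarray,
                              thr: float,
                              bin_width_cm: float = 0.25,
                              rs_floor: float = 20.0,
                              center_positions: np.ndarray | None = None,
                              ) -> RadiusEstimate:
    """Largest source-to-contact distance at which recording remains likely.

    Patches are sorted into half-open distance bins of 0.25 cm around
    each sampled contact; per bin the percentage of that bin's patches
    with |V| >= thr is the contact's RS at that radius.  The median over
    contacts is taken per bin, and the radius is the right edge of the
    farthest bin whose median RS is at least ``rs_floor`` percent.
    Radius 0 with a flag is returned when no bin passes.
    """
    rows = np.asarray(sample_contact_rows, dtype=np.int64)
    if center_positions is None:
        center_positions = patch_lf.patch_center_positions
    if patch_lf.contact_positions is None:
        raise ValueError("patch lead field has no contact positions")
    cpos = patch_lf.contact_positions[rows]
    dist_cm = np.linalg.norm(
        cpos[:, None, :] - center_positions[None, :, :], axis=-1) / 10.0
    rec = np.abs(patch_lf.matrix[rows]) >= thr       # (contacts, patches)
    bins = np.floor(dist_cm / bin_width_cm).astype(int)
    n_bins = int(bins.max()) + 1
    n_contacts = len(rows)
    rs = np.full((n_contacts, n_bins), np.nan)
    for i in range(n_contacts):
        total = np.bincount(bins[i], minlength=n_bins)
        hit = np.bincount(bins[i], weights=rec[i].astype(float),
                          minlength=n_bins)
        occ = total > 0
        rs[i, occ] = 100.0 * hit[occ] / total[occ]
    import warnings
    with warnings.catch_warnings():
        # bins occupied for no contact yield all-NaN columns by design
        warnings.simplefilter("ignore", RuntimeWarning)
        median = np.nanmedian(rs, axis=0)
    occupied = ~np.isnan(median)
    edges = (np.arange(n_bins) + 1) * bin_width_cm
    passing = occupied & (median >= rs_floor)
    if not passing.any():
        return RadiusEstimate(0.0, False, edges[occupied],
                              median[occupied], rs_floor, thr)
    radius = float(edges[np.flatnonzero(passing)[-1]])
    return RadiusEstimate(radius, True, edges[occupied],
                          median[occupied], rs_floor, thr)


def contact_sampling(cortex, region_labels: np.ndarray, per_region: int = 3,
                     seed: int | None = None,
                     expected_regions: int | None = None) -> np.ndarray:
    """Seeded random contact locations on the cortex, ``per_region`` points
    from each labelled subregion (area-weighted triangle choice, uniform
    point within the triangle).  With 35 regions per hemisphere and 3
    points each, this yields the standard 105 locations per hemisphere."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(region_labels)
    present = np.unique(labels)
    if expected_regions is not None:
        missing = set(range(expected_regions)) - set(int(v) for v in present)
        if missing:
            raise ValueError(f"regions with no elements: {sorted(missing)}")
    points = []
    for lab in present:
        faces = np.flatnonzero(labels == lab)
        w = cortex.areas[faces]
        chosen = rng.choice(faces, size=per_region, p=w / w.sum())
        u = rng.random((per_region, 1))
        v = rng.random((per_region, 1))
        flip = (u + v) > 1
        u, v = np.where(flip, 1 - u, u), np.where(flip, 1 - v, v)
        tri = cortex.triangle_vertices[chosen]
        points.append(tri[:, 0] + u * (tri[:, 1] - tri[:, 0])
                      + v * (tri[:, 2] - tri[:, 0]))
    return np.vstack(points)


# ---------------------------------------------------------------------------
# Trace statistics behind the thresholds
# ---------------------------------------------------------------------------

def common_average_reference(trace: SEEGTrace) -> SEEGTrace:
    """Subtract the across-channel mean at every sample."""
    if trace.voltages.shape[0] < 2:
        raise ValueError("common average reference needs >= 2 channels")
    v = trace.voltages - trace.voltages.mean(axis=0, keepdims=True)
    return SEEGTrace(voltages=v, sample_rate=trace.sample_rate,
                     spike_free_mask=trace.spike_free_mask.copy())


def noise_threshold(trace: SEEGTrace) -> float:
    """Discernibility floor: 4 x SD of spike-free samples (pooled over
    channels), in uV."""
    if not trace.spike_free_mask.any():
        raise ValueError("spike-free mask is empty")
    quiet = trace.voltages[:, trace.spike_free_mask]
    return 4.0 * float(quiet.std())


def spike_amplitude_stats(trace: SEEGTrace,
                          spike_windows: list[tuple[int, int]]) -> dict:
    """Per-spike maximum |V| over all channels, with the summary statistics
    used to pick thresholds (mean of maxima, 25th percentile with linear
    interpolation)."""
    if not spike_windows:
        raise ValueError("need at least one spike window")
    n = trace.voltages.shape[1]
    maxima = []
    for lo, hi in spike_windows:
        if lo < 0 or hi > n or lo >= hi:
            raise ValueError(f"spike window ({lo}, {hi}) outside the trace")
        maxima.append(float(np.abs(trace.voltages[:, lo:hi]).max()))
    maxima = np.array(maxima)
    return {
        "max_per_spike": maxima,
        "mean_max": float(maxima.mean()),
        "p25_max": float(np.percentile(maxima, 25)),
    }
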