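"""Parametric synthetic head geometry and sEEG-like voltage traces.

Patient-specific pipelines derive scalp, inner-skull and cortex surfaces
from imaging.  For development and testing this module generates an
analogous three-surface head from first principles: concentric
subdivided icospheres, with the cortex radially modulated by a product
of sinusoids in the spherical angles so that unambiguous gyri (outward
folds) and sulci (inward folds) exist.  A companion generator produces
intracranial-EEG-like voltage traces (Gaussian background noise plus
biphasic spike templates) for the noise-threshold and spike-amplitude
statistics, and a toy lead-field factory gives tiny matrices with
controllable magnitude-versus-distance structure for metric unit tests.

Every generator is fully deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import SurfaceMesh

__all__ = [
    "SyntheticHeadSpec",
    "TraceSpec",
    "HeadModel",
    "make_synthetic_head",
    "make_region_labels",
    "make_trace",
    "make_toy_leadfield",
]


@dataclass(frozen=True)
class SyntheticHeadSpec:
    """Parameters of the synthetic three-surface head (all lengths mm).

    The cortex radius in direction (theta, phi) is
    ``cortex_base_radius + fold_amplitude * sin(f*theta) * sin(f*phi)``
    with ``f = fold_frequency``; fold_amplitude 0 gives a sphere.
    Defaults approximate adult head dimensions: ~92 mm scalp radius,
    ~85 mm inner skull, cortex envelope 63-77 mm with ~7 mm deep folds.
    """

    scalp_radius: float = 92.0
    skull_radius: float = 85.0
    cortex_base_radius: float = 70.0
    fold_amplitude: float = 7.0
    fold_frequency: int = 6
    mesh_subdivision: int = 3
    midline_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    midline_normal: tuple[float, float, float] = (1.0, 0.0, 0.0)
    entry_cap_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    entry_cap_half_angle_deg: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if not (self.scalp_radius > self.skull_radius
                > self.cortex_base_radius + self.fold_amplitude >= 0):
            raise ValueError(
                "need scalp_radius > skull_radius > "
                "cortex_base_radius + fold_amplitude >= 0")
        if self.fold_amplitude < 0:
            raise ValueError("fold_amplitude must be >= 0")
        if self.mesh_subdivision < 2:
            raise ValueError("mesh_subdivision must be >= 2")
        if not (0.0 < self.entry_cap_half_angle_deg <= 90.0):
            raise ValueError("entry cap half-angle must be in (0, 90] deg")
        if abs(np.linalg.norm(self.midline_normal) - 1) > 1e-9:
            raise ValueError("midline_normal must be a unit vector")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


@dataclass
class HeadModel:
    """Scalp, inner-skull and cortex surfaces plus the midline plane and
    the scalp entry region used for trajectory sampling."""

    scalp: SurfaceMesh
    skull: SurfaceMesh
    cortex: SurfaceMesh
    midline_point: np.ndarray
    midline_normal: np.ndarray
    entry_cap_axis: np.ndarray
    entry_cap_half_angle_deg: float
    spec: SyntheticHeadSpec | None = None
    head_center: np.ndarray = field(
        default_factory=lambda: np.zeros(3))


def _icosphere(radius: float, subdivision: int) -> SurfaceMesh:
    m = trimesh.creation.icosphere(subdivisions=subdivision, radius=radius)
    return SurfaceMesh.from_trimesh(m)


def make_synthetic_head(spec: SyntheticHeadSpec) -> HeadModel:
    """Build the three-surface synthetic head from a spec.

    All surfaces are closed, outward-oriented subdivided icospheres; the
    cortex is radially perturbed by the spec's fold field.  Identical
    specs produce bit-identical meshes.
    """
    spec.validate()
    scalp = _icosphere(spec.scalp_radius, spec.mesh_subdivision)
    skull = _icosphere(spec.skull_radius, spec.mesh_subdivision)

    unit = _icosphere(1.0, spec.mesh_subdivision)
    v = unit.vertices
    theta = np.arccos(np.clip(v[:, 2], -1.0, 1.0))   # polar angle
    phi = np.arctan2(v[:, 1], v[:, 0])               # azimuth
    f = spec.fold_frequency
    r = spec.cortex_base_radius + spec.fold_amplitude * np.sin(f * theta) * np.sin(f * phi)
    cortex = SurfaceMesh(v * r[:, None], unit.faces)

    return HeadModel(
        scalp=scalp, skull=skull, cortex=cortex,
        midline_point=np.asarray(spec.midline_point, dtype=float),
        midline_normal=np.asarray(spec.midline_normal, dtype=float),
        entry_cap_axis=np.asarray(spec.entry_cap_axis, dtype=float),
        entry_cap_half_angle_deg=spec.entry_cap_half_angle_deg,
        spec=spec)


def make_region_labels(cortex: SurfaceMesh, midline_point: np.ndarray,
                       midline_normal: np.ndarray,
                       regions_per_hemisphere: int = 35) -> np.ndarray:
    """Deterministic per-triangle region labels emulating an atlas
    parcellation.

    Each hemisphere (sign of the signed distance to the midline plane)
    is split into quantile bands of the polar angle and, within each
    band, quantile sectors of azimuth, yielding ``regions_per_hemisphere``
    non-empty cells.  Labels are ``hemisphere * regions_per_hemisphere
    + cell``.
    """
    c = cortex.centroids
    side = ((c - midline_point) @ np.asarray(midline_normal) >= 0).astype(int)
    # factor regions into bands x sectors as near-square as possible
    n = regions_per_hemisphere
    bands = int(np.floor(np.sqrt(n)))
    while n % bands:
        bands -= 1
    sectors = n // bands
    labels = np.zeros(cortex.n_faces, dtype=np.int64)
    for hemi in (0, 1):
        idx = np.flatnonzero(side == hemi)
        if idx.size < n:
            raise ValueError("hemisphere has fewer faces than regions")
        z = c[idx, 2]
        band = np.minimum((np.argsort(np.argsort(z)) * bands) // idx.size,
                          bands - 1)
        for b in range(bands):
            sub = idx[band == b]
            az = np.arctan2(c[sub, 1], c[sub, 0])
            sec = np.minimum((np.argsort(np.argsort(az)) * sectors)
                             // sub.size, sectors - 1)
            labels[sub] = hemi * n + b * sectors + sec
    return labels


# ---------------------------------------------------------------------------
# Voltage traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceSpec:
    """Parameters of a synthetic sEEG-like voltage trace.

    Spikes are biphasic triangular pulses 60 ms wide with the stated
    peak amplitude, assigned round-robin to channels (spike k lands on
    channel k mod n_channels) so that common-average referencing does
    not cancel them.
    """

    n_channels: int = 4
    n_samples: int = 100_000
    sample_rate: float = 1000.0
    noise_sd: float = 50.0                       # microvolts
    spike_amplitudes: tuple[float, ...] = ()     # microvolts, peak
    spike_times: tuple[int, ...] = ()            # sample indices
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.spike_amplitudes) != len(self.spike_times):
            raise ValueError("one amplitude per spike time")
        for t in self.spike_times:
            if not (0 <= t < self.n_samples):
                raise ValueError("spike time outside the trace")


def _spike_template(amplitude: float, width_samples: int) -> np.ndarray:
    """Biphasic pulse: rise to +A at the centre, overshoot to -A/2, return."""
    w = max(width_samples, 4)
    q = w // 4
    nodes = np.array([0, 2 * q, 3 * q, 4 * q], dtype=float)
    vals = np.array([0.0, amplitude, -amplitude / 2.0, 0.0])
    t = np.arange(4 * q + 1, dtype=float)
    return np.interp(t, nodes, vals)


def make_trace(spec: TraceSpec):
    """Generate a synthetic trace; returns a ``sensitivity.SEEGTrace``.

    The spike-free mask excludes a window around every planted spike, so
    that the noise-threshold statistic (4 x SD of spike-free samples)
    can be evaluated without contamination.
    """
    from .sensitivity import SEEGTrace

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    volts = rng.normal(0.0, spec.noise_sd,
                       size=(spec.n_channels, spec.n_samples))
    mask = np.ones(spec.n_samples, dtype=bool)
    width = int(round(0.060 * spec.sample_rate))  # 60 ms
    for k, (amp, t0) in enumerate(zip(spec.spike_amplitudes,
                                      spec.spike_times)):
        tpl = _spike_template(amp, width)
        peak = 2 * (max(width, 4) // 4)     # template index of the +A peak
        start = t0 - peak
        lo, hi = max(start, 0), min(start + len(tpl), spec.n_samples)
        ch = k % spec.n_channels
        volts[ch, lo:hi] += tpl[lo - start:hi - start]
        mlo = max(t0 - len(tpl), 0)
        mhi = min(t0 + len(tpl), spec.n_samples)
        mask[mlo:mhi] = False
    return SEEGTrace(voltages=volts, sample_rate=spec.sample_rate,
                     spike_free_mask=mask)


# ---------------------------------------------------------------------------
# Toy lead fields
# ---------------------------------------------------------------------------

def make_toy_leadfield(n_contacts: int, n_sources: int, decay_law,
                       seed: int = 0):
    """Small deterministic lead field with controllable distance structure.

    Contacts sit on the z-axis at 3.5 mm pitch, sources on the x-axis at
    2 mm pitch; entry (i, j) is ``decay_law(distance_ij)`` (the law may
    optionally accept a seeded Generator as second argument).
    """
    from .forward import LeadField

    if n_contacts < 1 or n_sources < 1:
        raise ValueError("need at least one contact and one source")
    contacts = np.zeros((n_contacts, 3))
    contacts[:, 2] = np.arange(n_contacts) * 3.5
    sources = np.zeros((n_sources, 3))
    sources[:, 0] = np.arange(n_sources) * 2.0
    dist = np.linalg.norm(contacts[:, None, :] - sources[None, :, :], axis=-1)
    rng = np.random.default_rng(seed)
    try:
        matrix = np.asarray(decay_law(dist, rng), dtype=float)
    except TypeError:
        matrix = np.asarray(decay_law(dist), dtype=float)
    return LeadField(matrix=matrix, contact_positions=contacts,
                     source_ids=np.arange(n_sources),
                     source_positions=sources)
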