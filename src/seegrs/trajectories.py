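"""Candidate electrode trajectories: sampling, safety filters, collisions.

The search space is built from scalp insertion points and insertion
angles: each (entry, direction) pair defines an electrode *line*, which
is discretized into trajectories by sampling insertion depth at
multiples of the 3.5 mm contact pitch, keeping the total length under
10 cm.  Because depths and contacts share the same lattice, trajectories
on one line overlap in most of their contact points, which keeps the
number of distinct recording locations (and hence lead-field rows) small.

Safety filters mirror surgical constraints: implantation angle within
10 degrees of the scalp normal, clearance of at least 1.5 mm from the
sulci surface (a proxy for large vasculature) and 4 mm from the inner
skull (away from the insertion site) and from the midline plane.
Shafts are represented as 128 evenly spaced points both for the
clearance tests and for pairwise collision detection (< 4 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import DistanceIndex, SurfaceMesh

__all__ = [
    "ElectrodeSpec",
    "Trajectory",
    "TrajectorySet",
    "sample_entries",
    "sample_directions",
    "discretize_depths",
    "shaft_points",
    "filter_valid",
    "collision_matrix",
    "downsample_lines",
]

MAX_ANGLE_DEG = 10.0
MAX_LENGTH_MM = 100.0
SULCI_CLEARANCE_MM = 1.5
SKULL_CLEARANCE_MM = 4.0
MIDLINE_CLEARANCE_MM = 4.0
COLLISION_MM = 4.0
SHAFT_SAMPLES = 128


@dataclass(frozen=True)
class ElectrodeSpec:
    """Geometry of a 16-contact depth electrode (PMT-style): 2 mm contacts
    separated by 1.5 mm insulators, i.e. 3.5 mm centre-to-centre pitch;
    each contact is modelled as a single point at its centre."""

    n_contacts: int = 16
    contact_length: float = 2.0
    insulator_length: float = 1.5
    pitch: float = 3.5

    def __post_init__(self):
        if self.n_contacts < 2:
            raise ValueError("need at least 2 contacts")
        if abs(self.pitch - (self.contact_length + self.insulator_length)) > 1e-9:
            raise ValueError("pitch must equal contact + insulator length")

    @property
    def span(self) -> float:
        """Distance from first to last contact centre (mm)."""
        return (self.n_contacts - 1) * self.pitch


@dataclass
class Trajectory:
    """A single candidate electrode placement.

    Contacts are placed tip-first: the deepest contact centre sits at
    the tip, with the rest following outward at the pitch, so that
    trajectories of one line share a depth lattice.
    """

    line_id: int
    entry: np.ndarray       # (3,) mm, on the scalp
    direction: np.ndarray   # (3,) unit, into the head
    tip_depth: float        # mm along direction
    electrode: ElectrodeSpec = field(default_factory=ElectrodeSpec)

    def __post_init__(self):
        self.entry = np.asarray(self.entry, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            self.direction = self.direction / n

    @property
    def length(self) -> float:
        return float(self.tip_depth)

    @property
    def contact_points(self) -> np.ndarray:
        """(n_contacts, 3) contact centres, deepest first."""
        depths = self.tip_depth - np.arange(
            self.electrode.n_contacts) * self.electrode.pitch
        return self.entry[None, :] + depths[:, None] * self.direction[None, :]


def shaft_points(traj: Trajectory, n: int = SHAFT_SAMPLES) -> np.ndarray:
    """n points evenly spaced from entry to tip (inclusive)."""
    t = np.linspace(0.0, traj.tip_depth, n)
    return traj.entry[None, :] + t[:, None] * traj.direction[None, :]


@dataclass
class TrajectorySet:
    """Validated candidate trajectories with their pairwise collisions."""

    trajectories: list[Trajectory]
    collision: np.ndarray | None = None   # (n, n) bool, symmetric, False diag
    validity_log: dict[int, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trajectories)

    def contact_points(self) -> np.ndarray:
        """(n, n_contacts, 3) contact centres of all trajectories."""
        return np.stack([t.contact_points for t in self.trajectories])


# ---------------------------------------------------------------------------
# Sampling the search space
# ---------------------------------------------------------------------------

def sample_entries(scalp: SurfaceMesh, cap_axis: np.ndarray,
                   cap_half_angle_deg: float, n: int = 800,
                   seed: int | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-by-area sample of n scalp insertion points within a
    spherical-cap region, with inward surface normals attached."""
    axis = np.asarray(cap_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    center = scalp.vertices.mean(axis=0)
    d = scalp.centroids - center
    cosang = (d @ axis) / np.linalg.norm(d, axis=1)
    faces = np.flatnonzero(cosang >= np.cos(np.radians(cap_half_angle_deg)))
    if faces.size == 0:
        raise ValueError("entry cap does not intersect the scalp")
    rng = np.random.default_rng(seed)
    w = scalp.areas[faces]
    chosen = rng.choice(faces, size=n, p=w / w.sum())
    u = rng.random((n, 1))
    v = rng.random((n, 1))
    flip = (u + v) > 1
    u, v = np.where(flip, 1 - u, u), np.where(flip, 1 - v, v)
    tri = scalp.triangle_vertices[chosen]
    pts = tri[:, 0] + u * (tri[:, 1] - tri[:, 0]) + v * (tri[:, 2] - tri[:, 0])
    inward = -scalp.normals[chosen]
    return pts, inward


def sample_directions(normal: np.ndarray, max_angle_deg: float = MAX_ANGLE_DEG,
                      n: int = 366, seed: int | None = None) -> np.ndarray:
    """n unit vectors spread over the cone of half-angle ``max_angle_deg``
    about the inward normal: a deterministic Fibonacci spiral (uniform in
    solid angle), with a seeded common azimuth rotation when a seed is
    given."""
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    if max_angle_deg <= 0 or n == 1:
        return np.tile(normal, (max(n, 1), 1))
    cos_max = np.cos(np.radians(max_angle_deg))
    i = np.arange(n)
    cos_t = 1.0 - (1.0 - cos_max) * (i + 0.5) / n
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t ** 2))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = i * golden
    if seed is not None:
        phi = phi + np.random.default_rng(seed).uniform(0, 2 * np.pi)
    # orthonormal frame around the normal
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return (cos_t[:, None] * normal[None, :]
            + sin_t[:, None] * (np.cos(phi)[:, None] * e1[None, :]
                                + np.sin(phi)[:, None] * e2[None, :]))


def discretize_depths(entry: np.ndarray, direction: np.ndarray, line_id: int,
                      electrode: ElectrodeSpec | None = None,
                      max_length_mm: float = MAX_LENGTH_MM,
                      step_mm: float | None = None) -> list[Trajectory]:
    """Trajectories of one line at tip depths span, span+pitch, ...
    <= max_length.  All contacts lie between entry and tip; a 100 mm
    line yields 14 depth choices for the 16-contact electrode."""
    electrode = electrode or ElectrodeSpec()
    step = electrode.pitch if step_mm is None else step_mm
    span = electrode.span
    if max_length_mm < span:
        return []
    n_depths = int(np.floor((max_length_mm - span) / step + 1e-9)) + 1
    return [Trajectory(line_id=line_id, entry=entry, direction=direction,
                       tip_depth=span + k * step, electrode=electrode)
            for k in range(n_depths)]


# ---------------------------------------------------------------------------
# Safety filters
# ---------------------------------------------------------------------------

def _shaft_clears(index: DistanceIndex, pts: np.ndarray, clearance: float,
                  allowed: np.ndarray | None = None,
                  stride: int = 8) -> np.ndarray:
    """Exact per-shaft clearance decision against an indexed structure.

    Equivalent to testing all shaft points, but cheaper: a strided
    coarse pass decides most shafts because the distance to a fixed
    structure is 1-Lipschitz along the straight shaft, so the full-grid
    minimum can undercut the coarse minimum by at most ``stride`` times
    the sample spacing.  Only shafts inside that uncertainty band get
    the full-resolution check.
    """
    n, m = pts.shape[0], pts.shape[1]
    if allowed is None:
        allowed = np.ones((n, m), dtype=bool)
    spacing = (np.linalg.norm(pts[:, -1] - pts[:, 0], axis=1) / (m - 1))
    coarse_cols = np.r_[np.arange(0, m, stride), m - 1]
    d_c = index.min_distance(pts[:, coarse_cols].reshape(-1, 3)).reshape(n, -1)
    d_c = np.where(allowed[:, coarse_cols], d_c, np.inf)
    dmin_c = d_c.min(axis=1)
    valid = dmin_c >= clearance + stride * spacing   # provably clear
    invalid = dmin_c < clearance                     # coarse subset suffices
    undecided = ~valid & ~invalid
    if undecided.any():
        sub = pts[undecided].reshape(-1, 3)
        d = index.min_distance(sub).reshape(-1, m)
        d = np.where(allowed[undecided], d, np.inf)
        valid[np.flatnonzero(undecided)] = d.min(axis=1) >= clearance
    return valid


def filter_valid(trajectories: list[Trajectory],
                 sulci: SurfaceMesh | None,
                 skull: SurfaceMesh,
                 midline_point: np.ndarray, midline_normal: np.ndarray,
                 sulci_clearance_mm: float = SULCI_CLEARANCE_MM,
                 skull_clearance_mm: float = SKULL_CLEARANCE_MM,
                 midline_clearance_mm: float = MIDLINE_CLEARANCE_MM,
                 skull_entry_skip_mm: float = 15.0,
                 shaft_samples: int = SHAFT_SAMPLES) -> TrajectorySet:
    """Keep trajectories whose 128-point shafts clear all critical
    structures; rejected trajectories are logged with the first structure
    violated.

    The skull clearance is only enforced for shaft points farther than
    ``skull_entry_skip_mm`` from the entry: every electrode necessarily
    crosses the skull at its own insertion site, and the skip must cover
    that transit plus the clearance itself.
    """
    if not trajectories:
        return TrajectorySet(trajectories=[], validity_log={})
    pts = np.stack([shaft_points(t, shaft_samples) for t in trajectories])
    n, m = pts.shape[0], pts.shape[1]
    flat = pts.reshape(-1, 3)

    reject = {}
    ok = np.ones(n, dtype=bool)

    if sulci is not None and sulci.n_faces > 0 and sulci_clearance_mm > 0:
        bad = ~_shaft_clears(DistanceIndex(sulci), pts, sulci_clearance_mm)
        for i in np.flatnonzero(bad & ok):
            reject[i] = "sulci"
        ok &= ~bad

    if skull_clearance_mm > 0:
        depth = np.linalg.norm(pts - pts[:, :1, :], axis=-1)
        allowed = depth > skull_entry_skip_mm
        bad = ~_shaft_clears(DistanceIndex(skull), pts, skull_clearance_mm,
                             allowed=allowed)
        for i in np.flatnonzero(bad & ok):
            reject[i] = "skull"
        ok &= ~bad

    if midline_clearance_mm > 0:
        nrm = np.asarray(midline_normal, dtype=float)
        nrm = nrm / np.linalg.norm(nrm)
        sd = np.abs((flat - np.asarray(midline_point)) @ nrm).reshape(n, m)
        bad = sd.min(axis=1) < midline_clearance_mm
        for i in np.flatnonzero(bad & ok):
            reject[i] = "midline"
        ok &= ~bad

    kept = [t for i, t in enumerate(trajectories) if ok[i]]
    log = {int(i): r for i, r in reject.items()}
    return TrajectorySet(trajectories=kept, validity_log=log)


def collision_matrix(trajectories: list[Trajectory],
                     threshold_mm: float = COLLISION_MM,
                     samples_per_electrode: int = SHAFT_SAMPLES) -> np.ndarray:
    """Symmetric boolean matrix: a pair collides iff the minimum distance
    between their point representations is < threshold (strict)."""
    n = len(trajectories)
    out = np.zeros((n, n), dtype=bool)
    if n < 2:
        return out
    pts = np.stack([shaft_points(t, samples_per_electrode)
                    for t in trajectories])
    flat = pts.reshape(-1, 3)
    tree = cKDTree(flat)
    pairs = tree.query_pairs(threshold_mm, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(flat[pairs[:, 0]] - flat[pairs[:, 1]], axis=1)
        pairs = pairs[d < threshold_mm]
        ti = pairs // samples_per_electrode
        different = ti[:, 0] != ti[:, 1]
        ti = ti[different]
        out[ti[:, 0], ti[:, 1]] = True
        out[ti[:, 1], ti[:, 0]] = True
    return out


def downsample_lines(tset: TrajectorySet, target: int,
                     seed: int | None = None) -> TrajectorySet:
    """Randomly remove whole lines (all depths together) until the
    trajectory count is <= target; no-op if already within target."""
    if len(tset) <= target:
        return tset
    rng = np.random.default_rng(seed)
    line_ids = np.array([t.line_id for t in tset.trajectories])
    uniq = np.unique(line_ids)
    order = rng.permutation(uniq)
    removed: set[int] = set()
    count = len(tset)
    for lid in order:
        if count <= target:
            break
        members = int((line_ids == lid).sum())
        removed.add(int(lid))
        count -= members
    kept = [t for t in tset.trajectories if t.line_id not in removed]
    return TrajectorySet(trajectories=kept, collision=None,
                         validity_log=dict(tset.validity_log))
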