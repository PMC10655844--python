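"""Extended-dipole patch lead fields.

Interictal spikes are generated by centimetre-scale sheets of
synchronously active cortex, not by single dipoles.  A patch source of
fixed total surface area is therefore grown around every cortical
element, and the patch lead field is assembled by summing the per-dipole
lead-field columns of its members, each weighted by its triangle area,
then scaling by the neocortical dipole moment density.  The standard
grid covers patch areas of 6, 10 and 20 cm^2 and densities of 0.16,
0.465 and 0.77 nA*m/mm^2; the (10 cm^2, 0.465 nA*m/mm^2) pair is the
default source used in all analyses.

Unit bookkeeping: lead field in V/(A*m), triangle areas in mm^2,
density in nA*m/mm^2, assembled patch voltages in microvolts
(1 nA*m = 1e-9 A*m, 1 V = 1e6 uV, net factor 1e-3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .forward import LeadField
from .geometry import Patch, SurfaceMesh, grow_patch, patch_extent

__all__ = [
    "PATCH_AREAS_CM2",
    "MOMENT_DENSITIES",
    "DEFAULT_AREA_CM2",
    "DEFAULT_DENSITY",
    "PatchLeadField",
    "grow_patches",
    "build_patch_lead_field",
    "source_grid",
    "patch_extent_summary",
]

PATCH_AREAS_CM2 = (6.0, 10.0, 20.0)
MOMENT_DENSITIES = (0.16, 0.465, 0.77)   # nA*m / mm^2
DEFAULT_AREA_CM2 = 10.0
DEFAULT_DENSITY = 0.465

_NAM_TO_AM = 1e-9
_V_TO_UV = 1e6


@dataclass
class PatchLeadField:
    """Contacts x patches matrix of spike-peak voltages in microvolts."""

    matrix: np.ndarray                  # (n_contacts, n_patches) uV
    patch_area_cm2: float
    moment_density: float               # nA*m/mm^2
    patch_centers: np.ndarray           # (n_patches,) centre element ids
    patch_center_positions: np.ndarray  # (n_patches, 3) mm
    contact_positions: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.isfinite(self.matrix).all():
            raise ValueError("patch lead field contains non-finite entries")
        if self.matrix.shape[1] != len(self.patch_centers):
            raise ValueError("one column per patch required")

    @property
    def n_patches(self) -> int:
        return self.matrix.shape[1]


def grow_patches(mesh: SurfaceMesh, area_cm2: float,
                 centers: np.ndarray | None = None) -> list[Patch]:
    """Grow one patch of the given area around each centre element
    (default: every element of the mesh)."""
    if centers is None:
        centers = np.arange(mesh.n_faces)
    return [grow_patch(mesh, int(c), area_cm2) for c in centers]


def build_patch_lead_field(lead_field: LeadField, patches: list[Patch],
                           moment_density: float,
                           mesh: SurfaceMesh) -> PatchLeadField:
    """Assemble the patch lead field from per-dipole columns.

    Column j = sum over members k of patch j of
    ``L[:, k] * area_k(mm^2) * density(nA*m/mm^2)``, converted to uV.
    Exactly linear in the density.
    """
    col_of = {int(e): i for i, e in enumerate(lead_field.source_ids)}
    rows, cols, vals = [], [], []
    for j, patch in enumerate(patches):
        for k in patch.members:
            if int(k) not in col_of:
                raise ValueError(f"patch member {int(k)} not in lead field")
            rows.append(col_of[int(k)])
            cols.append(j)
            vals.append(mesh.areas[int(k)])
    weights = sparse.coo_matrix(
        (vals, (rows, cols)),
        shape=(lead_field.matrix.shape[1], len(patches))).tocsc()
    matrix = (lead_field.matrix @ weights) * (
        moment_density * _NAM_TO_AM * _V_TO_UV)
    centers = np.array([p.center_element for p in patches], dtype=np.int64)
    if lead_field.source_positions is not None:
        pos_of = {int(e): lead_field.source_positions[i]
                  for i, e in enumerate(lead_field.source_ids)}
        center_positions = np.array([pos_of[int(c)] for c in centers])
    else:
        center_positions = mesh.centroids[centers]
    area = float(np.mean([p.area_cm2 for p in patches])) if patches else 0.0
    return PatchLeadField(matrix=np.asarray(matrix),
                          patch_area_cm2=area,
                          moment_density=float(moment_density),
                          patch_centers=centers,
                          patch_center_positions=center_positions,
                          contact_positions=lead_field.contact_positions)


def source_grid(lead_field: LeadField, mesh: SurfaceMesh,
                areas: tuple[float, ...] = PATCH_AREAS_CM2,
                densities: tuple[float, ...] = MOMENT_DENSITIES,
                ) -> dict[tuple[float, float], PatchLeadField]:
    """All (area, density) patch lead fields — nine source types for the
    standard grid.  Patches are grown once per area; densities reuse
    them (columns differ only by the density ratio).  The returned dict
    maps (area_cm2, density) pairs; the default source is
    ``grid[DEFAULT_AREA_CM2, DEFAULT_DENSITY]`` when present."""
    grid: dict[tuple[float, float], PatchLeadField] = {}
    for area in areas:
        patches = grow_patches(mesh, area)
        base = build_patch_lead_field(lead_field, patches, 1.0, mesh)
        for density in densities:
            grid[(area, density)] = PatchLeadField(
                matrix=base.matrix * density,
                patch_area_cm2=float(area),
                moment_density=float(density),
                patch_centers=base.patch_centers,
                patch_center_positions=base.patch_center_positions,
                contact_positions=base.contact_positions)
    return grid


def patch_extent_summary(mesh: SurfaceMesh,
                         patches_by_area: dict[float, list[Patch]],
                         ) -> dict[float, float]:
    """Mean patch extent (cm) per area class.

    The extent of a patch is the mean Euclidean distance from its
    area-weighted centre of mass to its boundary vertices; extents are
    filled in on the Patch objects as a side effect.
    """
    out: dict[float, float] = {}
    for area, patches in patches_by_area.items():
        extents = []
        for p in patches:
            if p.extent_cm is None:
                p.extent_cm = patch_extent(mesh, p)
            extents.append(p.extent_cm)
        out[area] = float(np.mean(extents))
    return out
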