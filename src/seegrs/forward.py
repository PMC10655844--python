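"""Analytic dipole forward model and lead-field assembly.

Recorded sEEG voltages are linear in the source dipole moments; the
lead-field matrix collects, column by column, the potential each
unit-moment cortical dipole produces at every recording contact.  Here
the volume conductor is an unbounded homogeneous medium, for which the
current-dipole potential has the closed form

    V(r) = p . (r - r0) / (4 pi sigma |r - r0|^3),

with the voltage reference at infinity.  Patient-specific finite-element
lead fields can replace this model through the HDF5 import path; the
analytic model exists so that the whole planning chain is exercisable
without a FEM solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SurfaceMesh

__all__ = [
    "ConductivityModel",
    "DipoleSourceSet",
    "LeadField",
    "dipole_potential",
    "sources_from_cortex",
    "build_lead_field",
    "export_lead_field",
    "import_lead_field",
    "subtract_reference_contact",
]

_SINGULARITY_MM = 0.1
_MM = 1e-3  # metres per millimetre


@dataclass(frozen=True)
class ConductivityModel:
    """Homogeneous isotropic conductivity (S/m).

    0.33 S/m is the standard brain-tissue value used when a single
    compartment stands in for the full five-tissue head.
    """

    sigma: float = 0.33
    kind: str = "infinite_homogeneous"

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kind != "infinite_homogeneous":
            raise ValueError(f"unsupported conductor kind: {self.kind}")


@dataclass
class DipoleSourceSet:
    """One dipole per cortical element, oriented along the outward normal."""

    positions: np.ndarray      # (n, 3) mm
    orientations: np.ndarray   # (n, 3) unit vectors
    element_areas: np.ndarray  # (n,) mm^2
    element_ids: np.ndarray    # (n,) triangle indices

    def __post_init__(self):
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("orientations must be unit vectors")


@dataclass
class LeadField:
    """Contacts x sources matrix of potentials per unit dipole moment,
    in V/(A*m)."""

    matrix: np.ndarray             # (n_contacts, n_sources)
    contact_positions: np.ndarray  # (n_contacts, 3) mm
    source_ids: np.ndarray         # (n_sources,) element indices
    source_positions: np.ndarray | None = None  # (n_sources, 3) mm, optional

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.isfinite(self.matrix).all():
            raise ValueError("lead field contains non-finite entries")
        if self.matrix.shape[1] != len(self.source_ids):
            raise ValueError("column count must equal source count")
        if self.matrix.shape[0] != len(self.contact_positions):
            raise ValueError("row count must equal contact count")


def dipole_potential(position: np.ndarray, moment_vector: np.ndarray,
                     observation_points: np.ndarray,
                     model: ConductivityModel) -> np.ndarray:
    """Potential (V) of a current dipole at a set of observation points.

    ``position`` and ``observation_points`` are in mm, ``moment_vector``
    in A*m.  Points closer than 0.1 mm to the dipole raise a
    singularity error.
    """
    r0 = np.asarray(position, dtype=float) * _MM
    p = np.asarray(moment_vector, dtype=float)
    obs = np.atleast_2d(np.asarray(observation_points, dtype=float)) * _MM
    d = obs - r0
    dist = np.linalg.norm(d, axis=1)
    if np.any(dist < _SINGULARITY_MM * _MM):
        raise ValueError("observation point within 0.1 mm of the dipole")
    return (d @ p) / (4.0 * np.pi * model.sigma * dist ** 3)


def sources_from_cortex(cortex: SurfaceMesh) -> DipoleSourceSet:
    """One outward-pointing dipole at the centroid of every cortex triangle."""
    if np.isnan(cortex.normals).any():
        raise ValueError("cortex has degenerate triangles")
    return DipoleSourceSet(positions=cortex.centroids.copy(),
                           orientations=cortex.normals.copy(),
                           element_areas=cortex.areas.copy(),
                           element_ids=np.arange(cortex.n_faces))


def build_lead_field(sources: DipoleSourceSet, contacts: np.ndarray,
                     model: ConductivityModel,
                     chunk: int = 2048) -> LeadField:
    """Assemble the lead field: column k is the potential of a unit-moment
    dipole at source k, evaluated at all contacts.  Linear in the moment
    by construction."""
    contacts = np.atleast_2d(np.asarray(contacts, dtype=float))
    n_c, n_s = len(contacts), len(sources.positions)
    matrix = np.empty((n_c, n_s))
    r_c = contacts * _MM
    for s in range(0, n_s, chunk):
        pos = sources.positions[s:s + chunk] * _MM
        ori = sources.orientations[s:s + chunk]
        d = r_c[:, None, :] - pos[None, :, :]          # (c, s, 3)
        dist = np.linalg.norm(d, axis=-1)
        if np.any(dist < _SINGULARITY_MM * _MM):
            raise ValueError("a contact lies within 0.1 mm of a source")
        matrix[:, s:s + chunk] = (d * ori[None, :, :]).sum(-1) \
            / (4.0 * np.pi * model.sigma * dist ** 3)
    return LeadField(matrix=matrix, contact_positions=contacts,
                     source_ids=sources.element_ids.copy(),
                     source_positions=sources.positions.copy())


def subtract_reference_contact(lead_field: LeadField,
                               reference_row: int) -> LeadField:
    """Re-reference: subtract one contact's row from all rows (post-hoc
    stand-in for a grounded reference electrode)."""
    m = lead_field.matrix - lead_field.matrix[reference_row][None, :]
    return LeadField(matrix=m,
                     contact_positions=lead_field.contact_positions.copy(),
                     source_ids=lead_field.source_ids.copy(),
                     source_positions=None if lead_field.source_positions
                     is None else lead_field.source_positions.copy())


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

_UNITS = "V_per_Am"


def export_lead_field(lead_field: LeadField, path,
                      sigma_S_per_m: float | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=lead_field.matrix)
        f.create_dataset("contacts", data=lead_field.contact_positions)
        f.create_dataset("source_ids", data=lead_field.source_ids)
        if lead_field.source_positions is not None:
            f.create_dataset("source_positions",
                             data=lead_field.source_positions)
        f.attrs["units"] = _UNITS
        if sigma_S_per_m is not None:
            f.attrs["sigma_S_per_m"] = float(sigma_S_per_m)


def import_lead_field(path) -> LeadField:
    """Load an externally computed lead field; validates shapes, units and
    finiteness so FEM exports can stand in for the analytic model."""
    import h5py

    with h5py.File(path, "r") as f:
        for name in ("matrix", "contacts", "source_ids"):
            if name not in f:
                raise ValueError(f"lead-field container missing /{name}")
        units = f.attrs.get("units")
        if units != _UNITS:
            raise ValueError(
                f"lead-field units must be {_UNITS!r}, got {units!r}")
        matrix = f["matrix"][()]
        contacts = f["contacts"][()]
        source_ids = f["source_ids"][()]
        source_positions = (f["source_positions"][()]
                            if "source_positions" in f else None)
    if not np.isfinite(matrix).all():
        raise ValueError("lead-field matrix contains non-finite values")
    return LeadField(matrix=matrix, contact_positions=contacts,
                     source_ids=source_ids,
                     source_positions=source_positions)
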