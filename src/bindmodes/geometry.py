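"""Superposition and geometric descriptors.

Kabsch least-squares superposition underlies every RMSD quantity; RMSF uses
a time-averaged reference after one alignment pass; SASA is Shrake-Rupley
with Bondi van der Waals radii.  All lengths are Angstrom, areas Angstrom^2,
times ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajio import Selection, Trajectory, resolve_selection

# Bondi (1964) van der Waals radii, Angstrom.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}


class GeometryError(ValueError):
    """Raised for degenerate geometric input."""


@dataclass
class RigidTransform:
    """Proper rotation + translation: x -> rotation @ x + translation."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rotation=rot_inv, translation=-rot_inv @ self.translation)


@dataclass
class SeriesResult:
    """A per-frame (or per-atom/residue) scalar series with provenance."""

    metric: str
    index: np.ndarray  # frame times (ps) or atom/residue labels
    values: np.ndarray
    selection: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise GeometryError(f"{self.metric}: non-finite values")


@dataclass
class PairwiseMatrix:
    """Symmetric frame-by-frame RMSD matrix (zero diagonal)."""

    matrix: np.ndarray
    times_ps: np.ndarray
    selection: str = ""


def _as_indices(traj: Trajectory, selection) -> np.ndarray:
    if selection is None:
        return np.arange(traj.n_atoms)
    if isinstance(selection, Selection):
        return selection.indices
    if isinstance(selection, str):
        return resolve_selection(traj, selection).indices
    return np.asarray(selection, dtype=int)


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares (Kabsch) fit of ``mobile`` onto ``reference``.

    Returns the optimal proper rigid transform and the minimized RMSD.
    Requires >= 3 non-collinear points; reflections are excluded by the
    determinant correction.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise GeometryError(
            f"selection size mismatch: {mobile.shape[0]} vs {reference.shape[0]} atoms"
        )
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 atoms")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    # collinearity check: centered point cloud must span a plane
    s_mob = np.linalg.svd(mob_c, compute_uv=False)
    if s_mob[1] < 1e-8 * max(s_mob[0], 1.0):
        raise GeometryError("degenerate (collinear) fit selection")
    cov = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = reference.mean(axis=0) - rot @ mobile.mean(axis=0)
    fitted = mob_c @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref_c) ** 2, axis=1))))
    return RigidTransform(rotation=rot, translation=trans), rmsd


def rmsd_series(
    traj: Trajectory,
    fit_selection,
    measure_selection=None,
    reference_frame: int = 0,
) -> SeriesResult:
    """RMSD over time: fit each frame on ``fit_selection``, measure on
    ``measure_selection`` without re-fitting (ligand-aligned-to-protein
    convention).  When ``measure_selection`` is None the fit selection is
    measured."""
    fit_idx = _as_indices(traj, fit_selection)
    meas_idx = fit_idx if measure_selection is None else _as_indices(traj, measure_selection)
    if not (0 <= reference_frame < traj.n_frames):
        raise GeometryError(f"reference frame {reference_frame} out of range")
    ref = traj.coordinates[reference_frame]
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        tf, _ = superpose(traj.coordinates[i][fit_idx], ref[fit_idx])
        moved = tf.apply(traj.coordinates[i][meas_idx])
        values[i] = np.sqrt(np.mean(np.sum((moved - ref[meas_idx]) ** 2, axis=1)))
    name = "rmsd" if measure_selection is None else "rmsd(fit!=measure)"
    return SeriesResult(metric=name, index=traj.times_ps, values=values,
                        selection=str(getattr(fit_selection, "expression", fit_selection)))


def pairwise_rmsd(traj: Trajectory, fit_selection) -> PairwiseMatrix:
    """All-against-all superposition RMSD between sampled frames."""
    if traj.n_frames < 2:
        raise GeometryError("pairwise RMSD needs at least 2 frames")
    idx = _as_indices(traj, fit_selection)
    coords = traj.coordinates[:, idx]
    n = traj.n_frames
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, r = superpose(coords[j], coords[i])
            mat[i, j] = mat[j, i] = r
    return PairwiseMatrix(matrix=mat, times_ps=traj.times_ps,
                          selection=str(getattr(fit_selection, "expression", fit_selection)))


def rmsf(
    traj: Trajectory,
    selection=None,
    fit_selection=None,
    per_residue: bool = False,
) -> SeriesResult:
    """Root-mean-square fluctuation about the time-averaged structure.

    Frames are first aligned (on ``fit_selection``, default: the measured
    selection) to frame 0, the mean structure is formed, and one further
    alignment pass onto that mean fixes the reference.  Per-residue output
    averages the per-atom values over each residue's selected atoms.
    """
    if traj.n_frames < 2:
        raise GeometryError("RMSF needs at least 2 frames")
    meas_idx = _as_indices(traj, selection)
    fit_idx = meas_idx if fit_selection is None else _as_indices(traj, fit_selection)

    # pass 1: align everything onto frame 0, form the time-averaged structure
    first_pass = np.empty((traj.n_frames, traj.n_atoms, 3))
    for i in range(traj.n_frames):
        tf, _ = superpose(traj.coordinates[i][fit_idx], traj.coordinates[0][fit_idx])
        first_pass[i] = tf.apply(traj.coordinates[i])
    mean_full = first_pass.mean(axis=0)
    # pass 2: re-align onto the averaged structure, measure fluctuations
    aligned = np.empty((traj.n_frames, len(meas_idx), 3))
    for i in range(traj.n_frames):
        tf, _ = superpose(traj.coordinates[i][fit_idx], mean_full[fit_idx])
        aligned[i] = tf.apply(traj.coordinates[i][meas_idx])
    mean_pos = aligned.mean(axis=0)
    sq = np.sum((aligned - mean_pos) ** 2, axis=2)  # frames x atoms
    per_atom = np.sqrt(sq.mean(axis=0))
    if not per_residue:
        return SeriesResult(metric="rmsf", index=meas_idx.astype(float),
                            values=per_atom, selection="per-atom")
    resids = traj.topology.resids[meas_idx]
    uniq = np.unique(resids)
    vals = np.array([per_atom[resids == r].mean() for r in uniq])
    return SeriesResult(metric="rmsf", index=uniq.astype(float),
                        values=vals, selection="per-residue")


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    coords: np.ndarray,
    elements,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """Shrake-Rupley solvent-accessible surface area (Angstrom^2).

    Each atom's accessible sphere (vdW radius + probe) is sampled with a
    golden-spiral lattice; points buried inside any neighbour's accessible
    sphere are discarded.  Additive over non-overlapping molecules.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    elements = [str(e) for e in np.atleast_1d(np.asarray(elements, dtype=object))]
    missing = sorted({e for e in elements if e not in VDW_RADII})
    if missing:
        raise GeometryError(f"no van der Waals radius for element(s) {missing}")
    radii = np.array([VDW_RADII[e] for e in elements]) + probe_radius
    n_atoms = len(coords)
    unit = _sphere_points(n_points)
    total = 0.0
    for i in range(n_atoms):
        pts = coords[i] + radii[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n_atoms):
            if j == i:
                continue
            sep = np.linalg.norm(coords[i] - coords[j])
            if sep < 1e-9:
                # coincident spheres: the surface counts once — the larger
                # sphere (ties: lower index) keeps it
                if radii[j] > radii[i] + 1e-9 or (
                    abs(radii[j] - radii[i]) <= 1e-9 and j < i
                ):
                    accessible[:] = False
                    break
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        total += 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return float(total)


def sasa_series(
    traj: Trajectory,
    selection=None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SeriesResult:
    """Per-frame SASA of a selection (the report names the selection)."""
    idx = _as_indices(traj, selection)
    elements = traj.topology.elements[idx]
    values = np.array([
        sasa(traj.coordinates[f][idx], elements, probe_radius, n_points)
        for f in range(traj.n_frames)
    ])
    return SeriesResult(metric="sasa", index=traj.times_ps, values=values,
                        selection=str(getattr(selection, "expression", selection)))


def center_of_mass(coords: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if masses is None:
        return coords.mean(axis=0)
    masses = np.asarray(masses, dtype=float)
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def com_distance_series(
    traj: Trajectory,
    group_a,
    group_b,
    mass_weighted: bool = True,
) -> SeriesResult:
    """Per-frame distance between the centers of mass of two atom groups.

    This is the collective variable used to map ligand/helix motions
    (e.g. helix-12 residue COM to helix-5/helix-11 residue COM).
    """
    ia = _as_indices(traj, group_a)
    ib = _as_indices(traj, group_b)
    if len(ia) == 0 or len(ib) == 0:
        raise GeometryError("COM groups must be non-empty")
    masses = traj.topology.masses if mass_weighted else None
    ma = masses[ia] if mass_weighted else None
    mb = masses[ib] if mass_weighted else None
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        ca = center_of_mass(traj.coordinates[f][ia], ma)
        cb = center_of_mass(traj.coordinates[f][ib], mb)
        values[f] = np.linalg.norm(ca - cb)
    return SeriesResult(metric="com_distance", index=traj.times_ps, values=values,
                        selection=f"{group_a} | {group_b}")
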