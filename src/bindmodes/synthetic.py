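"""Ground-truthed synthetic systems for every analysis stage.

:func:`generate` emits a small receptor-like helical polymer with a bound
rigid ligand that hops between a handful of planted metastable binding
modes, scheduled hydrogen bonds with exact target occupancies, slow
rigid-body drift of the whole complex and per-atom thermal jitter.  The
files written (PDB topology + DCD coordinates + JSON ground truth) are the
exact formats the readers consume, so tests exercise real parsers.

:func:`toy_walker` runs an overdamped Langevin walker on an analytic 1-D
double well while depositing well-tempered bias hills; it provides an
independent oracle for the FES reconstruction machinery.

What this emulates — and what it does not: the generator reproduces the
*statistical* structure that binding-mode clustering assumes (distinct
long-lived ligand arrangements, decorrelated noise, on/off contacts); it
has no force field, no solvent and no realistic stereochemistry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fes import HillLog
from .trajio import Topology, Trajectory, write_pdb, write_trajectory


class SyntheticError(ValueError):
    """Raised for infeasible generator specifications."""


@dataclass
class SyntheticSpec:
    """Parameters of a planted-ground-truth toy system.

    Defaults plant three binding modes at the 61/23/16 frame split over
    1000 frames with a 5 Angstrom mode separation against 0.3 Angstrom
    per-atom thermal noise — well-separated (> 5 sigma) metastable modes.
    """

    n_residues: int = 12
    ligand_atoms: int = 6
    n_modes: int = 3
    mode_fractions: tuple = (0.61, 0.23, 0.16)
    mode_separation: float = 5.0  # Angstrom between adjacent mode anchors
    noise_sigma: float = 0.3  # per-axis Gaussian jitter, Angstrom
    noise_corr: float = 0.7  # AR(1) frame-to-frame jitter correlation
    noise_breath: float = 0.35  # slow fractional modulation of jitter amplitude
    hbond_schedule: dict = field(default_factory=dict)  # (donor_resid, acceptor_resid) -> target %
    n_frames: int = 1000
    dt_ps: float = 10.0
    drift_sigma: float = 0.02  # per-frame rigid-body random-walk step, Angstrom
    min_dwell: int = 10  # frames; keeps modes metastable, not i.i.d.
    first_resid: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 10:
            raise SyntheticError("need at least 10 frames")
        if self.n_modes < 1 or len(self.mode_fractions) != self.n_modes:
            raise SyntheticError("one occupancy fraction per mode required")
        if not np.isclose(sum(self.mode_fractions), 1.0):
            raise SyntheticError("mode fractions must sum to 1")
        if self.mode_separation <= 0:
            raise SyntheticError("mode separation must be positive")
        for pair, target in self.hbond_schedule.items():
            if not 0.0 <= target <= 100.0:
                raise SyntheticError(f"H-bond target {target}% for {pair} infeasible")


@dataclass
class GroundTruth:
    """Planted truth accompanying a generated system."""

    mode_labels: np.ndarray  # per-frame planted mode (0-based)
    hbond_masks: dict  # (donor_resid, acceptor_resid) -> per-frame bool array
    mode_displacements: np.ndarray  # (n_modes, 3) ligand anchor offsets
    dt_ps: float

    def to_json(self, path) -> None:
        payload = {
            "mode_labels": self.mode_labels.tolist(),
            "hbond_masks": {f"{d}-{a}": m.astype(int).tolist()
                            for (d, a), m in self.hbond_masks.items()},
            "mode_displacements": self.mode_displacements.tolist(),
            "dt_ps": self.dt_ps,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        masks = {}
        for key, m in payload["hbond_masks"].items():
            d, a = key.split("-")
            masks[(int(d), int(a))] = np.array(m, dtype=bool)
        return cls(
            mode_labels=np.array(payload["mode_labels"], dtype=int),
            hbond_masks=masks,
            mode_displacements=np.array(payload["mode_displacements"]),
            dt_ps=float(payload["dt_ps"]),
        )


# ---------------------------------------------------------------------------
# Topology construction
# ---------------------------------------------------------------------------

_RES_CYCLE = ["ALA", "SER", "VAL", "LEU", "THR", "GLY"]


def _build_topology(spec: SyntheticSpec) -> tuple[Topology, np.ndarray]:
    """Helical backbone (N, H, CA, C, O per residue) + side-chain donor or
    acceptor atoms on scheduled residues + a rigid chain ligand.

    Returns the topology and the reference coordinates (mode 0, no noise).
    """
    donors = {d for d, _ in spec.hbond_schedule}
    acceptors = {a for _, a in spec.hbond_schedule}
    names, elements, resids, resnames, chains = [], [], [], [], []
    bonds: list[tuple[int, int]] = []
    coords: list[np.ndarray] = []

    # ideal-helix-like CA trace: rise 1.5 A, radius 2.3 A, 100 deg/residue
    def ca_pos(i: int) -> np.ndarray:
        ang = np.deg2rad(100.0 * i)
        return np.array([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * i])

    prev_c = None
    for i in range(spec.n_residues):
        resid = spec.first_resid + i
        resname = _RES_CYCLE[i % len(_RES_CYCLE)]
        ca = ca_pos(i)
        base = len(names)
        local = {
            "N": ca + np.array([-1.2, 0.3, -0.5]),
            "H": ca + np.array([-1.9, 0.9, -0.8]),
            "CA": ca,
            "C": ca + np.array([1.3, 0.2, 0.4]),
            "O": ca + np.array([1.6, 1.3, 0.7]),
        }
        for name, pos in local.items():
            names.append(name)
            elements.append("H" if name == "H" else name[0])
            resids.append(resid)
            resnames.append(resname)
            chains.append("A")
            coords.append(pos)
        bonds += [(base + 0, base + 1), (base + 0, base + 2),
                  (base + 2, base + 3), (base + 3, base + 4)]
        if prev_c is not None:
            bonds.append((prev_c, base + 0))
        prev_c = base + 3
        # side-chain donor group (ND1-HD1) / acceptor oxygen (OE1) where scheduled
        if resid in donors:
            nd = len(names)
            for name, element, off in [("ND1", "N", np.array([0.0, -1.6, 0.0])),
                                       ("HD1", "H", np.array([0.0, -2.6, 0.0]))]:
                names.append(name)
                elements.append(element)
                resids.append(resid)
                resnames.append(resname)
                chains.append("A")
                coords.append(ca + off)
            bonds += [(base + 2, nd), (nd, nd + 1)]
        if resid in acceptors:
            oe = len(names)
            names.append("OE1")
            elements.append("O")
            resids.append(resid)
            resnames.append(resname)
            chains.append("A")
            coords.append(ca + np.array([0.0, 1.8, 0.0]))
            bonds.append((base + 2, oe))

    # rigid chain ligand, resname LIG, parked near the helix axis
    lig_resid = spec.first_resid + spec.n_residues
    lig_base = len(names)
    # park the ligand far enough out that the deepest planted mode stays
    # clear of the receptor
    lig_anchor = np.array([4.0 + 2.0 * spec.mode_separation, 0.0,
                           0.75 * spec.n_residues])
    for j in range(spec.ligand_atoms):
        names.append(f"C{j + 1}")
        elements.append("C")
        resids.append(lig_resid)
        resnames.append("LIG")
        chains.append("L")
        coords.append(lig_anchor + np.array([1.4 * j, 0.3 * (j % 2), 0.0]))
        if j:
            bonds.append((lig_base + j - 1, lig_base + j))

    topo = Topology(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        chains=np.array(chains, dtype=object),
        bonds=np.array(bonds, dtype=int),
    )
    return topo, np.array(coords)


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

def _mode_schedule(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-frame mode labels: exact fraction counts, contiguous dwellings.

    Each mode's frame quota is split into blocks of at least ``min_dwell``
    frames and the blocks are shuffled, giving Markov-like metastability
    with exactly reproduced occupancy fractions (to rounding).
    """
    counts = np.rint(np.asarray(spec.mode_fractions) * spec.n_frames).astype(int)
    counts[0] += spec.n_frames - counts.sum()  # absorb rounding in the top mode
    if np.any(counts < 0):
        raise SyntheticError("mode fractions infeasible at this frame count")
    blocks: list[tuple[int, int]] = []  # (mode, length)
    for mode, count in enumerate(counts):
        remaining = count
        while remaining > 0:
            if remaining < 2 * spec.min_dwell:
                length = remaining
            else:
                length = int(rng.integers(spec.min_dwell,
                                          min(remaining - spec.min_dwell,
                                              4 * spec.min_dwell) + 1))
            blocks.append((mode, length))
            remaining -= length
    rng.shuffle(blocks)
    labels = np.concatenate([
        np.full(length, mode, dtype=int) for mode, length in blocks
    ]) if blocks else np.zeros(0, dtype=int)
    return labels


def _exact_count_mask(target_pct: float, n_frames: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Boolean mask with exactly round(target% * n) frames on."""
    n_on = int(round(target_pct / 100.0 * n_frames))
    mask = np.zeros(n_frames, dtype=bool)
    mask[rng.choice(n_frames, size=n_on, replace=False)] = True
    return mask


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def generate(
    spec: SyntheticSpec,
    outdir=None,
) -> tuple[Trajectory, GroundTruth]:
    """Build the toy system; optionally write PDB/DCD/JSON into ``outdir``.

    Deterministic given ``spec.seed``: the same spec always produces
    byte-identical files.
    """
    rng = np.random.default_rng(spec.seed)
    topo, ref_coords = _build_topology(spec)
    n_atoms = topo.n_atoms
    labels = _mode_schedule(spec, rng)

    # planted ligand displacement per mode: spread along distinct directions
    # planted poses step along the receptor-ligand axis so every
    # ligand-residue distance descriptor separates the modes; adjacent
    # anchors are exactly ``mode_separation`` apart
    steps = np.array([0.0, 1.0, -1.0, 2.0, -2.0])
    if spec.n_modes > len(steps):
        raise SyntheticError(f"at most {len(steps)} planted modes supported")
    displacements = np.zeros((spec.n_modes, 3))
    displacements[:, 0] = spec.mode_separation * steps[: spec.n_modes]

    lig_idx = np.flatnonzero(topo.resnames.astype(str) == "LIG")
    # induced-fit response: the last quarter of the receptor (a "lid")
    # shifts with the binding mode, so backbone / interacting-residue RMSD
    # descriptors carry mode information just as the ligand distances do
    lid_resids = set(range(spec.first_resid + (3 * spec.n_residues) // 4,
                           spec.first_resid + spec.n_residues))
    lid_idx = np.array([i for i in range(topo.n_atoms)
                        if int(topo.resids[i]) in lid_resids])
    lid_amp = 0.6 * spec.mode_separation * np.arange(spec.n_modes)
    lid_dir = np.array([0.0, 1.0, 0.0])
    name_index = {
        (int(r), str(n)): i
        for i, (r, n) in enumerate(zip(topo.resids, topo.names))
    }
    hb_masks = {
        pair: _exact_count_mask(target, spec.n_frames, rng)
        for pair, target in spec.hbond_schedule.items()
    }

    coords = np.empty((spec.n_frames, n_atoms, 3))
    drift = np.zeros(3)
    # AR(1) jitter: stationary sigma = noise_sigma, short-lag correlation as
    # in trajectories sampled a few correlation times apart; the initial
    # frame shares the same statistics instead of sitting exactly on the
    # noiseless reference
    rho = spec.noise_corr
    jitter = rng.normal(0.0, spec.noise_sigma, size=(n_atoms, 3))
    # slow global "breathing": the jitter amplitude itself wanders, as the
    # collective soft modes of a real protein make it do, so per-frame RMSD
    # values spread over a band instead of collapsing onto a razor-thin
    # plateau that would turn the reference frame into an outlier
    breath = 0.0
    for f in range(spec.n_frames):
        frame = ref_coords.copy()
        frame[lig_idx] += displacements[labels[f]]
        frame[lid_idx] += lid_amp[labels[f]] * lid_dir
        if spec.noise_sigma > 0:
            if f:
                jitter = rho * jitter + np.sqrt(1.0 - rho ** 2) * rng.normal(
                    0.0, spec.noise_sigma, size=(n_atoms, 3))
                breath = 0.95 * breath + np.sqrt(1.0 - 0.95 ** 2) * rng.normal()
            amplitude = max(0.2, 1.0 + spec.noise_breath * breath)
            frame += amplitude * jitter
        # scheduled H-bonds override jitter on the four participating atoms
        for (d_res, a_res), mask in hb_masks.items():
            nd = name_index[(d_res, "ND1")]
            hd = name_index[(d_res, "HD1")]
            oe = name_index[(a_res, "OE1")]
            anchor = ref_coords[nd]
            axis = ref_coords[oe] - ref_coords[nd]
            axis = axis / np.linalg.norm(axis)
            frame[nd] = anchor
            if mask[f]:
                frame[hd] = anchor + 1.0 * axis  # linear N-H...O
                frame[oe] = anchor + 2.9 * axis  # inside 3.5 A / 150 deg
            else:
                frame[hd] = anchor + 1.0 * axis
                frame[oe] = anchor + 5.0 * axis  # well outside the cutoff
        drift = drift + rng.normal(0.0, spec.drift_sigma, size=3)
        frame += drift
        coords[f] = frame

    traj = Trajectory(topology=topo, coordinates=coords, dt_ps=spec.dt_ps)
    truth = GroundTruth(
        mode_labels=labels,
        hbond_masks=hb_masks,
        mode_displacements=displacements,
        dt_ps=spec.dt_ps,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_pdb(traj, outdir / "topology.pdb")
        write_trajectory(traj, outdir / "trajectory.dcd")
        truth.to_json(outdir / "ground_truth.json")
    return traj, truth


# ---------------------------------------------------------------------------
# Metadynamics toy walker
# ---------------------------------------------------------------------------

@dataclass
class DoubleWell:
    """Quartic double well V(x) = barrier * ((x/half_sep)^2 - 1)^2.

    Minima at +-half_sep (Angstrom); barrier height at x = 0 (kcal/mol).
    """

    barrier: float = 3.0
    half_sep: float = 1.0

    def __post_init__(self) -> None:
        if self.barrier <= 0:
            raise SyntheticError("barrier must be positive")

    def potential(self, x):
        return self.barrier * ((np.asarray(x) / self.half_sep) ** 2 - 1.0) ** 2

    def force(self, x):
        u = x / self.half_sep
        return -4.0 * self.barrier * u * (u ** 2 - 1.0) / self.half_sep


def toy_walker(
    well: DoubleWell | None = None,
    n_steps: int = 60000,
    seed: int = 0,
    kt: float = 0.596,  # kcal/mol at ~300 K
    hill_height: float = 0.4,  # kcal/mol initial height
    hill_width: float = 0.20,  # Angstrom
    hill_stride: int = 100,  # steps between depositions
    bias_factor: float = 6.0,  # well-tempered gamma
    dt: float = 0.01,  # reduced-time integration step
    grid_bounds: tuple = (-2.5, 2.5),
    grid_bins: int = 500,
    x0: float | None = None,
) -> tuple[HillLog, np.ndarray, DoubleWell]:
    """Overdamped Langevin walker with well-tempered hill deposition.

    Hills start at ``hill_height`` and decay as exp(-V_bias/dT) with
    dT = (gamma - 1) T, the well-tempered schedule.  Returns the hill log,
    the CV time series and the analytic well (the exact surface oracle).
    """
    well = well or DoubleWell()
    rng = np.random.default_rng(seed)
    lo, hi = grid_bounds
    grid = np.linspace(lo, hi, grid_bins)
    bias = np.zeros(grid_bins)
    delta_t = (bias_factor - 1.0) * kt
    x = -well.half_sep if x0 is None else x0
    xs = np.empty(n_steps)
    times, centers, heights = [], [], []
    sigma_step = np.sqrt(2.0 * kt * dt)
    for step in range(n_steps):
        # bias force by finite difference on the grid
        gi = np.clip((x - lo) / (hi - lo) * (grid_bins - 1), 1, grid_bins - 2)
        i0 = int(gi)
        bias_force = -(bias[i0 + 1] - bias[i0 - 1]) / (2.0 * (grid[1] - grid[0]))
        x = x + (well.force(x) + bias_force) * dt + sigma_step * rng.normal()
        x = float(np.clip(x, lo + 1e-6, hi - 1e-6))
        xs[step] = x
        if (step + 1) % hill_stride == 0:
            gi = int(np.clip((x - lo) / (hi - lo) * (grid_bins - 1), 0, grid_bins - 1))
            h = hill_height * np.exp(-bias[gi] / delta_t)
            bias += h * np.exp(-((grid - x) ** 2) / (2.0 * hill_width ** 2))
            times.append((step + 1) * dt)
            centers.append(x)
            heights.append(h)
    hills = HillLog(
        times_ps=np.array(times),
        centers=np.array(centers),
        heights=np.array(heights),
        widths=np.full(len(times), hill_width),
    )
    return hills, xs, well
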