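"""Topology/trajectory containers, standard-format I/O and atom selections.

Internally coordinates are in Angstrom and times in picoseconds; every file
format is converted on read (MDAnalysis handles the unit conversions for
PDB/DCD/XTC).  Frame indexing is 0-based in code; user-facing reports print
1-based frame numbers together with the simulation time.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# Standard amino-acid residue names used to separate protein from ligand.
PROTEIN_RESNAMES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS HID HIE HIP ILE LEU LYS MET PHE
    PRO SER THR TRP TYR VAL""".split()
)

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

# Average atomic masses (amu) for the elements the package handles.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
}


class SelectionError(ValueError):
    """Raised when a selection expression cannot be resolved."""


class TrajectoryError(ValueError):
    """Raised for malformed or inconsistent topology/trajectory input."""


def infer_element(atom_name: str) -> str:
    """Guess the element from a PDB-style atom name.

    Two-letter elements (Cl, Br) are recognized first; otherwise the first
    alphabetic character wins (``CA`` -> carbon, ``1HB`` -> hydrogen).
    """
    stripped = atom_name.strip().upper()
    stripped = re.sub(r"^[0-9]+", "", stripped)
    if not stripped:
        raise TrajectoryError(f"cannot infer element from atom name {atom_name!r}")
    if stripped[:2] in ("CL", "BR"):
        return stripped[:2].capitalize()
    return stripped[0]


@dataclass
class Topology:
    """Atom metadata plus bonds and donor/acceptor flags.

    Atom indices are 0-based and contiguous.  ``donor_flags`` marks heavy
    atoms (N/O) that carry at least one bonded hydrogen; ``acceptor_flags``
    marks all N/O heavy atoms.
    """

    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    bonds: np.ndarray  # (n_bonds, 2) int

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.chains = np.asarray(self.chains, dtype=object)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        n = self.n_atoms
        if self.bonds.size and (self.bonds.min() < 0 or self.bonds.max() >= n):
            raise TrajectoryError("bond references a non-existent atom index")
        for arr, label in [
            (self.elements, "elements"),
            (self.resids, "resids"),
            (self.resnames, "resnames"),
            (self.chains, "chains"),
        ]:
            if len(arr) != n:
                raise TrajectoryError(f"{label} length {len(arr)} != n_atoms {n}")
        self._validate_hydrogens()

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def _validate_hydrogens(self) -> None:
        heavy_neighbours = {i: 0 for i in np.flatnonzero(self.elements == "H")}
        for a, b in self.bonds:
            if self.elements[a] == "H" and self.elements[b] != "H":
                heavy_neighbours[a] += 1
            if self.elements[b] == "H" and self.elements[a] != "H":
                heavy_neighbours[b] += 1
        bad = [i for i, c in heavy_neighbours.items() if c != 1]
        if bad:
            raise TrajectoryError(
                f"hydrogens {bad[:5]} do not have exactly one bonded heavy atom"
            )

    @property
    def masses(self) -> np.ndarray:
        try:
            return np.array([ATOMIC_MASSES[str(e).upper()] for e in self.elements])
        except KeyError as exc:  # pragma: no cover - defensive
            raise TrajectoryError(f"no mass for element {exc}") from exc

    def bonded_hydrogens(self) -> dict[int, list[int]]:
        """Map heavy-atom index -> indices of its bonded hydrogens."""
        out: dict[int, list[int]] = {}
        for a, b in self.bonds:
            if self.elements[a] == "H" and self.elements[b] != "H":
                out.setdefault(int(b), []).append(int(a))
            elif self.elements[b] == "H" and self.elements[a] != "H":
                out.setdefault(int(a), []).append(int(b))
        return out

    @property
    def donor_flags(self) -> np.ndarray:
        flags = np.zeros(self.n_atoms, dtype=bool)
        for heavy in self.bonded_hydrogens():
            if self.elements[heavy] in ("N", "O"):
                flags[heavy] = True
        return flags

    @property
    def acceptor_flags(self) -> np.ndarray:
        return np.isin(self.elements.astype(str), ("N", "O"))

    def is_protein(self) -> np.ndarray:
        return np.isin(self.resnames.astype(str), list(PROTEIN_RESNAMES))


@dataclass
class Trajectory:
    """Coordinates over time (Angstrom) with a fixed storage interval (ps)."""

    topology: Topology
    coordinates: np.ndarray  # (n_frames, n_atoms, 3) float
    dt_ps: float

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryError(
                f"coordinate array must be frames x atoms x 3, got {self.coordinates.shape}"
            )
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise TrajectoryError(
                f"trajectory has {self.coordinates.shape[1]} atoms but topology "
                f"has {self.topology.n_atoms}"
            )
        if self.dt_ps <= 0:
            raise TrajectoryError("time step must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ps


@dataclass
class Selection:
    """A resolved atom selection: the expression plus its atom index list."""

    expression: str
    indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# File I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _topology_from_universe(u) -> Topology:
    import MDAnalysis as mda  # noqa: F401 - deferred heavy import

    atoms = u.atoms
    names = [a.name for a in atoms]
    try:
        elements = [str(e).capitalize() if str(e).strip() else infer_element(n)
                    for e, n in zip(atoms.elements, names)]
    except Exception:
        elements = [infer_element(n) for n in names]
    try:
        chains = [a.chainID if a.chainID.strip() else "A" for a in atoms]
    except Exception:
        chains = ["A"] * len(atoms)
    try:
        bonds = np.array([[b[0].index, b[1].index] for b in u.bonds], dtype=int)
    except Exception:
        bonds = np.empty((0, 2), dtype=int)
    return Topology(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array([a.resid for a in atoms], dtype=int),
        resnames=np.array([a.resname for a in atoms], dtype=object),
        chains=np.array(chains, dtype=object),
        bonds=bonds if bonds.size else np.empty((0, 2), dtype=int),
    )


def load_system(topology_path, trajectory_path=None, dt_ps: float | None = None) -> Trajectory:
    """Read a PDB topology plus an optional DCD/XTC coordinate trajectory.

    Parameters
    ----------
    topology_path : path-like
        PDB file; CONECT records, when present, populate the bond list.
    trajectory_path : path-like, optional
        DCD or XTC coordinates.  When omitted the PDB's own coordinates
        (possibly multi-model) are used.
    dt_ps : float, optional
        Override the time step between stored frames.  When omitted the
        value recorded in the trajectory file is used (1 ps fallback for
        formats that store none).
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FileNotFoundError(topology_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory_path is None:
            u = mda.Universe(str(topology_path))
        else:
            trajectory_path = Path(trajectory_path)
            if not trajectory_path.exists():
                raise FileNotFoundError(trajectory_path)
            try:
                u = mda.Universe(str(topology_path), str(trajectory_path))
            except ValueError as exc:
                # MDAnalysis raises on atom-count mismatch; re-raise with counts
                u_top = mda.Universe(str(topology_path))
                raise TrajectoryError(
                    f"topology {topology_path.name} has {len(u_top.atoms)} atoms "
                    f"but trajectory {trajectory_path.name} does not match: {exc}"
                ) from exc
        topo = _topology_from_universe(u)
        n_frames = len(u.trajectory)
        coords = np.empty((n_frames, topo.n_atoms, 3), dtype=float)
        times = np.empty(n_frames, dtype=float)
        for i, ts in enumerate(u.trajectory):
            coords[i] = ts.positions  # MDAnalysis positions are Angstrom
            times[i] = ts.time
    if dt_ps is None:
        if n_frames > 1 and np.all(np.diff(times) > 0):
            dt_ps = float(np.mean(np.diff(times)))
        else:
            dt_ps = 1.0
    return Trajectory(topology=topo, coordinates=coords, dt_ps=float(dt_ps))


def write_pdb(traj: Trajectory, path, frame: int = 0) -> None:
    """Write one frame as PDB (with CONECT records for the stored bonds)."""
    import MDAnalysis as mda

    topo = traj.topology
    n = topo.n_atoms
    resids_unique, res_index = np.unique(topo.resids, return_inverse=True)
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=len(resids_unique),
        atom_resindex=res_index,
        trajectory=True,
    )
    u.add_TopologyAttr("names", topo.names.astype(str))
    u.add_TopologyAttr("elements", topo.elements.astype(str))
    first_atom = [int(np.flatnonzero(res_index == r)[0]) for r in range(len(resids_unique))]
    u.add_TopologyAttr("resnames", [str(topo.resnames[i]) for i in first_atom])
    u.add_TopologyAttr("resids", resids_unique)
    u.add_TopologyAttr("chainIDs", topo.chains.astype(str))
    u.add_TopologyAttr("occupancies", np.ones(n))
    u.add_TopologyAttr("tempfactors", np.zeros(n))
    if topo.bonds.size:
        u.add_TopologyAttr("bonds", [tuple(b) for b in topo.bonds])
    u.atoms.positions = traj.coordinates[frame]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path), bonds="all" if topo.bonds.size else None)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write coordinates as DCD or XTC (chosen by file extension)."""
    import MDAnalysis as mda

    topo = traj.topology
    resids_unique, res_index = np.unique(topo.resids, return_inverse=True)
    u = mda.Universe.empty(
        n_atoms=topo.n_atoms,
        n_residues=len(resids_unique),
        atom_resindex=res_index,
        trajectory=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topo.n_atoms, dt=traj.dt_ps) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.coordinates[i]
                u.trajectory.ts.dt = traj.dt_ps
                u.trajectory.ts.time = i * traj.dt_ps
                u.trajectory.ts.frame = i
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Frame sampling
# ---------------------------------------------------------------------------

def sample_frames(traj: Trajectory, stride_ps: float) -> Trajectory:
    """Down-sample to (approximately) one frame per ``stride_ps``.

    The achievable stride is the nearest integer multiple of the storage
    interval; the returned trajectory's ``dt_ps`` reports it.  Decorrelating
    frames before clustering is the usual reason to call this.
    """
    if stride_ps < traj.dt_ps - 1e-9:
        raise TrajectoryError(
            f"requested stride {stride_ps} ps is below the trajectory's native "
            f"resolution of {traj.dt_ps} ps per stored frame"
        )
    step = max(1, int(round(stride_ps / traj.dt_ps)))
    return Trajectory(
        topology=traj.topology,
        coordinates=traj.coordinates[::step],
        dt_ps=traj.dt_ps * step,
    )


# ---------------------------------------------------------------------------
# Selection mini-grammar
# ---------------------------------------------------------------------------
#
#   expr     := term (("and" | "or") term)*
#   term     := ["not"] atom
#   atom     := "(" expr ")" | keyword
#   keyword  := "all" | "protein" | "ligand" | "backbone"
#             | "resid"   range+          e.g. resid 288  |  resid 280:290
#             | "resname" NAME+
#             | "name"    NAME+
#             | "chain"   ID+
#
# "and" binds tighter than "or".

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)]


class _Parser:
    def __init__(self, topo: Topology, expression: str):
        self.topo = topo
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.pos = 0

    def _peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _next(self):
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def _error(self, msg: str, col: int) -> SelectionError:
        return SelectionError(f"{msg} at position {col} in {self.expression!r}")

    def parse(self) -> np.ndarray:
        mask = self._expr()
        if self.pos < len(self.tokens):
            tok, col = self.tokens[self.pos]
            raise self._error(f"unexpected token {tok!r}", col)
        return mask

    def _expr(self) -> np.ndarray:
        mask = self._and_expr()
        while self._peek() == "or":
            self._next()
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._term()
        while self._peek() == "and":
            self._next()
            mask = mask & self._term()
        return mask

    def _term(self) -> np.ndarray:
        if self._peek() == "not":
            self._next()
            return ~self._term()
        return self._atom()

    def _atom(self) -> np.ndarray:
        if self._peek() is None:
            raise self._error("unexpected end of expression", len(self.expression))
        tok, col = self._next()
        topo = self.topo
        if tok == "(":
            mask = self._expr()
            if self._peek() != ")":
                raise self._error("missing closing parenthesis", col)
            self._next()
            return mask
        if tok == "all":
            return np.ones(topo.n_atoms, dtype=bool)
        if tok == "protein":
            return topo.is_protein()
        if tok == "ligand":
            return ~topo.is_protein()
        if tok == "backbone":
            return topo.is_protein() & np.isin(topo.names.astype(str), list(BACKBONE_NAMES))
        if tok == "resid":
            return self._values(col, self._resid_mask)
        if tok == "resname":
            return self._values(col, lambda v: topo.resnames.astype(str) == v.upper())
        if tok == "name":
            return self._values(col, lambda v: topo.names.astype(str) == v.upper())
        if tok == "chain":
            return self._values(col, lambda v: topo.chains.astype(str) == v)
        raise self._error(f"unknown token {tok!r}", col)

    _KEYWORDS = {"and", "or", "not", "all", "protein", "ligand", "backbone",
                 "resid", "resname", "name", "chain", "(", ")"}

    def _values(self, col: int, one_value) -> np.ndarray:
        mask = np.zeros(self.topo.n_atoms, dtype=bool)
        seen = False
        while self._peek() is not None and self._peek() not in self._KEYWORDS:
            val, _ = self._next()
            mask |= one_value(val)
            seen = True
        if not seen:
            raise self._error("keyword requires at least one value", col)
        return mask

    def _resid_mask(self, value: str) -> np.ndarray:
        resids = self.topo.resids
        if ":" in value:
            lo_s, hi_s = value.split(":", 1)
            try:
                lo, hi = int(lo_s), int(hi_s)
            except ValueError as exc:
                raise SelectionError(f"bad residue range {value!r}") from exc
            return (resids >= lo) & (resids <= hi)
        try:
            return resids == int(value)
        except ValueError as exc:
            raise SelectionError(f"bad residue id {value!r}") from exc


def resolve_selection(obj, expression: str) -> Selection:
    """Resolve a selection expression on a Topology or Trajectory.

    The grammar supports ``all``, ``protein``, ``ligand``, ``backbone``
    (protein N/CA/C/O), ``resid`` (single ids or ``lo:hi`` ranges),
    ``resname``, ``name``, ``chain``, combined with ``and``/``or``/``not``
    and parentheses.  Resolution is deterministic: indices come back sorted.
    """
    topo = obj.topology if isinstance(obj, Trajectory) else obj
    mask = _Parser(topo, expression).parse()
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        raise SelectionError(f"selection {expression!r} matches no atoms")
    return Selection(expression=expression, indices=indices)
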