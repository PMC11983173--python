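"""Hydrogen-bond / salt-bridge detection, occupancy and network comparison.

A hydrogen bond is reported when the donor-acceptor heavy-atom distance is
at most ``d_cut`` (default 3.5 A) and the donor-H-acceptor angle is at
least ``angle_cut`` (default 150 deg) for some hydrogen on the donor.
Salt bridges (Arg/Lys side-chain N vs Glu/Asp side-chain O) use a plain
N...O distance criterion (default 4.0 A) and share the occupancy machinery.

Occupancy aggregates at the residue-pair level: a pair counts as present in
a frame if any contributing atom pair satisfies the criterion, because the
quantities of interest (and the published tables the format mirrors) are
residue pairs such as R357-E460.  Pairs never detected are simply absent
("NOB", not observed, in comparison output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajio import Topology, Trajectory

ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "HID": "H", "HIE": "H", "HIP": "H",
    "ILE": "I", "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# side-chain atoms eligible for the salt-bridge criterion
_BASIC_N = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2"),
            "HIP": ("ND1", "NE2")}
_ACIDIC_O = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}


class HBondError(ValueError):
    """Raised for topologies unusable by the geometric criterion."""


def _residue_tag(resname: str, resid: int) -> str:
    return f"{ONE_LETTER.get(str(resname).upper(), 'X')}{int(resid)}"


@dataclass(frozen=True)
class InteractionKey:
    """Canonical residue-pair interaction identity.

    For salt bridges the two residues are sorted so R357-E460 and E460-R357
    compare equal; hydrogen bonds keep donor -> acceptor direction.
    """

    donor: str  # e.g. "R357"
    acceptor: str  # e.g. "E460"
    kind: str = "hbond"  # "hbond" | "salt_bridge"
    atoms: tuple = ()

    @staticmethod
    def make(donor_resname, donor_resid, acc_resname, acc_resid,
             kind="hbond", atoms=()) -> "InteractionKey":
        a = _residue_tag(donor_resname, donor_resid)
        b = _residue_tag(acc_resname, acc_resid)
        if kind == "salt_bridge" and b < a:
            a, b = b, a
        return InteractionKey(donor=a, acceptor=b, kind=kind, atoms=tuple(atoms))

    @property
    def pair(self) -> str:
        return f"{self.donor}-{self.acceptor}"

    def residue_key(self) -> "InteractionKey":
        """Drop atom-name detail; used for residue-level aggregation."""
        return InteractionKey(self.donor, self.acceptor, self.kind, ())


@dataclass
class OccupancyTable:
    """Per residue-pair interaction occupancy (% of analyzed frames)."""

    system: str
    occupancies: dict  # InteractionKey -> float in [0, 100]
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise HBondError("occupancy table needs at least one analyzed frame")
        for key, occ in self.occupancies.items():
            if not 0.0 <= occ <= 100.0:
                raise HBondError(f"occupancy {occ} for {key.pair} outside [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"system": self.system, "donor": k.donor, "acceptor": k.acceptor,
             "class": k.kind, "occupancy_pct": v}
            for k, v in sorted(self.occupancies.items(),
                               key=lambda kv: -kv[1])
        ]
        return pd.DataFrame(rows, columns=["system", "donor", "acceptor",
                                           "class", "occupancy_pct"])


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _donor_triples(topo: Topology) -> tuple[np.ndarray, np.ndarray]:
    """(donor heavy index, hydrogen index) pairs for every N/O-H."""
    donors, hydrogens = [], []
    for heavy, hs in topo.bonded_hydrogens().items():
        if topo.elements[heavy] in ("N", "O"):
            for h in hs:
                donors.append(heavy)
                hydrogens.append(h)
    return np.array(donors, dtype=int), np.array(hydrogens, dtype=int)


def detect_hbonds(
    coords: np.ndarray,
    topology: Topology,
    d_cut: float = 3.5,
    angle_cut: float = 150.0,
    restrict: set | None = None,
) -> set:
    """Hydrogen bonds present in a single frame (residue-level keys).

    ``restrict``, when given, limits reporting to interactions where both
    residues are in the set of residue ids.
    """
    donors, hydrogens = _donor_triples(topology)
    if len(donors) == 0:
        raise HBondError(
            "topology contains no N/O-bonded hydrogens; the geometric "
            "hydrogen-bond criterion requires explicit hydrogens"
        )
    acceptors = np.flatnonzero(topology.acceptor_flags)
    coords = np.asarray(coords, dtype=float)
    found: set = set()
    d_pos = coords[donors]  # (nd, 3)
    h_pos = coords[hydrogens]
    a_pos = coords[acceptors]  # (na, 3)
    # donor-acceptor heavy-atom distances
    dist = np.linalg.norm(d_pos[:, None, :] - a_pos[None, :, :], axis=2)
    dh = h_pos - d_pos  # donor->H
    cos_cut = np.cos(np.deg2rad(angle_cut))
    for di in range(len(donors)):
        close = np.flatnonzero(dist[di] <= d_cut)
        for aj in close:
            a_idx = int(acceptors[aj])
            d_idx = int(donors[di])
            if a_idx == d_idx:
                continue
            if topology.resids[a_idx] == topology.resids[d_idx]:
                continue  # intra-residue contacts are not of interest
            ha = a_pos[aj] - h_pos[di]
            denom = np.linalg.norm(dh[di]) * np.linalg.norm(ha)
            if denom == 0:
                continue
            # D-H-A angle is the angle at H; wide angles mean small cosines
            cos_angle = np.dot(-dh[di], ha) / denom
            if cos_angle <= cos_cut:
                if restrict is not None and not (
                    topology.resids[d_idx] in restrict
                    and topology.resids[a_idx] in restrict
                ):
                    continue
                found.add(InteractionKey.make(
                    topology.resnames[d_idx], topology.resids[d_idx],
                    topology.resnames[a_idx], topology.resids[a_idx],
                    kind="hbond",
                    atoms=(str(topology.names[d_idx]), str(topology.names[a_idx])),
                ))
    return found


def detect_salt_bridges(
    coords: np.ndarray,
    topology: Topology,
    d_cut: float = 4.0,
    restrict: set | None = None,
) -> set:
    """Salt bridges (basic side-chain N vs acidic side-chain O <= d_cut)."""
    coords = np.asarray(coords, dtype=float)
    resnames = topology.resnames.astype(str)
    names = topology.names.astype(str)
    basic = [i for i in range(topology.n_atoms)
             if names[i] in _BASIC_N.get(resnames[i], ())]
    acidic = [i for i in range(topology.n_atoms)
              if names[i] in _ACIDIC_O.get(resnames[i], ())]
    found: set = set()
    for bi in basic:
        for ai in acidic:
            if topology.resids[bi] == topology.resids[ai]:
                continue
            if np.linalg.norm(coords[bi] - coords[ai]) <= d_cut:
                if restrict is not None and not (
                    topology.resids[bi] in restrict
                    and topology.resids[ai] in restrict
                ):
                    continue
                found.add(InteractionKey.make(
                    resnames[bi], topology.resids[bi],
                    resnames[ai], topology.resids[ai],
                    kind="salt_bridge",
                    atoms=(names[bi], names[ai]),
                ))
    return found


def occupancy(
    traj: Trajectory,
    d_cut: float = 3.5,
    angle_cut: float = 150.0,
    salt_bridge_cut: float | None = None,
    restrict: set | None = None,
    system: str = "system",
) -> OccupancyTable:
    """Percentage of sampled frames in which each residue pair interacts.

    A residue pair is present in a frame when any of its atom pairs meets
    the criterion (max-over-atom-pairs aggregation).  Setting
    ``salt_bridge_cut`` additionally tracks salt bridges as a separate
    interaction class.
    """
    if traj.n_frames < 1:
        raise HBondError("occupancy needs at least one frame")
    counts: dict = {}
    for f in range(traj.n_frames):
        frame_keys = {k.residue_key()
                      for k in detect_hbonds(traj.coordinates[f], traj.topology,
                                             d_cut, angle_cut, restrict)}
        if salt_bridge_cut is not None:
            frame_keys |= {k.residue_key()
                           for k in detect_salt_bridges(traj.coordinates[f],
                                                        traj.topology,
                                                        salt_bridge_cut, restrict)}
        for key in frame_keys:
            counts[key] = counts.get(key, 0) + 1
    occ = {k: 100.0 * c / traj.n_frames for k, c in counts.items()}
    return OccupancyTable(system=system, occupancies=occ, n_frames=traj.n_frames)


# ---------------------------------------------------------------------------
# Thresholding and cross-system comparison
# ---------------------------------------------------------------------------

def stable_interactions(table: OccupancyTable, threshold: float = 60.0) -> set:
    """Interactions at or above the stability threshold (inclusive >=)."""
    if not 0.0 < threshold <= 100.0:
        raise HBondError(f"threshold {threshold} outside (0, 100]")
    return {k for k, v in table.occupancies.items() if v >= threshold}


def compare_networks(
    tables: list[OccupancyTable],
    threshold: float = 60.0,
) -> tuple[set, dict]:
    """Shared stable core vs system-specific stable interactions.

    Returns ``(shared, differential)`` where ``shared`` holds the keys
    stable in every system and ``differential`` maps each system label to
    its stable keys not in the shared core.
    """
    if len(tables) < 2:
        raise HBondError("network comparison needs at least two systems")
    stables = {t.system: stable_interactions(t, threshold) for t in tables}
    shared = set.intersection(*stables.values())
    differential = {sys: s - shared for sys, s in stables.items()}
    return shared, differential


def comparison_table(
    tables: list[OccupancyTable],
    keys: list | None = None,
) -> pd.DataFrame:
    """Occupancy matrix residue-pair x system, 'NOB' for never-observed.

    ``keys`` restricts/orders the rows; by default all pairs seen in any
    system appear, ordered by max occupancy.
    """
    if keys is None:
        seen: dict = {}
        for t in tables:
            for k, v in t.occupancies.items():
                seen[k] = max(seen.get(k, 0.0), v)
        keys = [k for k, _ in sorted(seen.items(), key=lambda kv: -kv[1])]
    rows = []
    for k in keys:
        row = {"residues_pair": k.pair, "class": k.kind}
        for t in tables:
            v = t.occupancies.get(k)
            row[t.system] = "NOB" if v is None else f"{v:.2f}%"
        rows.append(row)
    return pd.DataFrame(rows)
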