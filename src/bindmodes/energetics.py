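"""Binding-energy combination and cluster-weighted aggregation.

The package never computes MM-GBSA / DFT-D3 / ANI energies itself: those
come from external scorers as per-structure tables (CSV).  Here they are
combined into binding energies

    dG_b = G_complex - G_ligand - G_receptor          (difference form)

optionally rescored by a linear two-backend combiner

    dG_b = alpha * dG_DFT + beta * dG_ANI + gamma

and aggregated over cluster centroids with the clusters' exact frame
fractions as weights.  More negative dG_b means stronger predicted
binding; reports sort ascending.  All energies are kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class EnergyError(ValueError):
    """Raised for incomplete or inconsistent energy input."""


@dataclass
class EnergyRecord:
    """Component energies for one structure (frame, centroid or pose)."""

    structure_id: str
    complex_energy: float
    ligand_energy: float
    receptor_energy: float
    backend: str = "MM-GBSA"

    def __post_init__(self) -> None:
        comps = (self.complex_energy, self.ligand_energy, self.receptor_energy)
        if any(c is None or not np.isfinite(c) for c in comps):
            raise EnergyError(
                f"structure {self.structure_id!r}: all three component "
                f"energies (complex, ligand, receptor) must be finite"
            )


@dataclass
class RescoreCoefficients:
    """alpha/beta (dimensionless) and gamma (kcal/mol) of the linear combiner.

    The optimized values are external inputs; ``provenance`` must say where
    they came from.  Defaults (1, 0, 0) pass the first backend through.
    """

    alpha: float = 1.0
    beta: float = 0.0
    gamma: float = 0.0
    provenance: str = "identity passthrough (no rescoring)"

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.alpha, self.beta, self.gamma])):
            raise EnergyError("rescoring coefficients must be finite")
        if not self.provenance:
            raise EnergyError("rescoring coefficients require a provenance note")


@dataclass
class WeightedEnergySummary:
    """Per-centroid binding energies and their cluster-weighted mean."""

    values: np.ndarray  # per-centroid dG_b, kcal/mol
    weights: np.ndarray  # normalized fractions, sum 1
    weighted_mean: float


def binding_energy(rec: EnergyRecord) -> float:
    """dG_b = complex - ligand - receptor (kcal/mol)."""
    return rec.complex_energy - rec.ligand_energy - rec.receptor_energy


def rescore_mlani(dg_dft, dg_ani, coef: RescoreCoefficients) -> np.ndarray | float:
    """Linear two-backend combination: alpha*dG_DFT + beta*dG_ANI + gamma.

    Statistically meaningful use needs more than one configuration; the
    function itself is elementwise and accepts scalars or arrays.
    """
    dg_dft = np.asarray(dg_dft, dtype=float)
    dg_ani = np.asarray(dg_ani, dtype=float)
    if dg_dft.shape != dg_ani.shape:
        raise EnergyError("DFT and ANI energy sets must cover the same structures")
    out = coef.alpha * dg_dft + coef.beta * dg_ani + coef.gamma
    return float(out) if out.ndim == 0 else out


def weighted_average(values, weights) -> WeightedEnergySummary:
    """Cluster-weighted mean binding energy.

    Weights are the clusters' exact frame fractions (not the rounded W%);
    they are renormalized to sum to 1, so equal weights give the plain
    mean.  Clusters with higher weights contribute proportionally more.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape or values.ndim != 1:
        raise EnergyError(
            f"need one weight per centroid value, got {values.shape} values "
            f"and {weights.shape} weights"
        )
    if np.any(weights < 0):
        raise EnergyError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise EnergyError("weights sum to zero")
    w = weights / total
    return WeightedEnergySummary(
        values=values, weights=w, weighted_mean=float(np.dot(w, values))
    )


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

def read_component_table(path) -> list[EnergyRecord]:
    """Read (id, complex, ligand, receptor[, backend]) rows from CSV."""
    df = pd.read_csv(path)
    required = {"id", "complex", "ligand", "receptor"}
    missing = required - set(df.columns)
    if missing:
        raise EnergyError(f"energy table missing column(s) {sorted(missing)}")
    return [
        EnergyRecord(
            structure_id=str(row["id"]),
            complex_energy=float(row["complex"]),
            ligand_energy=float(row["ligand"]),
            receptor_energy=float(row["receptor"]),
            backend=str(row.get("backend", "MM-GBSA")),
        )
        for _, row in df.iterrows()
    ]


def summary_frame(records: list[EnergyRecord]) -> pd.DataFrame:
    """Per-structure dG_b table sorted ascending (strongest binder first)."""
    df = pd.DataFrame(
        {
            "id": [r.structure_id for r in records],
            "dG_b_kcal_mol": [binding_energy(r) for r in records],
            "backend": [r.backend for r in records],
        }
    )
    return df.sort_values("dG_b_kcal_mol", kind="stable").reset_index(drop=True)
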