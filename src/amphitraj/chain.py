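"""Acyl-chain descriptors: deuterium order parameters, tail radius of
gyration, and head-to-terminal-carbon distance series.

The deuterium order parameter of tail carbon *i* is

    S_CD(i) = ⟨ (3 cos²θ − 1) / 2 ⟩,

θ the angle between a C–H bond of carbon *i* and the membrane normal, the
average running over frames, ligand copies, and that carbon's C–H bonds.
S_CD is bounded in [−0.5, 1]: −0.5 for bonds perpendicular to the normal,
1 for parallel, 0 under isotropic disorder.

The membrane normal is taken as the z axis (bilayer convention of the
generator and of typical membrane simulations); an arbitrary normal can be
passed.  The radius of gyration is unweighted over the tail carbons only —
head-group oxygens are excluded — matching the "radius of gyration of the
carbon tail" reading; set ``atoms`` explicitly to change that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Trajectory, minimum_image_distance
from .schema import LigandSchema
from .selection import Selection, resolve

__all__ = [
    "OrderParameterProfile",
    "ChainShapeSeries",
    "order_parameters",
    "radius_of_gyration",
    "head_to_tail_distance",
]


@dataclass
class OrderParameterProfile:
    carbons: list[str]
    s_cd: np.ndarray  # per-carbon mean
    stderr: np.ndarray  # SE over ligand × frame samples
    n_samples: np.ndarray
    used_hydrogen_fallback: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "carbon": self.carbons,
                "s_cd": self.s_cd,
                "stderr": self.stderr,
                "n_samples": self.n_samples,
            }
        )


@dataclass
class ChainShapeSeries:
    """Per-frame, per-ligand scalar series (Rg or a distance), with pooled
    and per-ligand summaries."""

    times_ns: np.ndarray
    values: np.ndarray  # (n_frames, n_ligands)
    quantity: str

    def summary(self, per_ligand_means: bool = False) -> dict:
        """Pooled statistics; ``per_ligand_means=True`` averages each ligand
        first and summarises the ligand means."""
        v = self.values.mean(axis=0) if per_ligand_means else self.values.ravel()
        return {
            "quantity": self.quantity,
            "mean": float(np.mean(v)),
            "std": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            "min": float(np.min(self.values)),
            "max": float(np.max(self.values)),
        }

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"ligand_{i}" for i in range(self.values.shape[1])])
        df.insert(0, "time_ns", self.times_ns)
        return df


def _ligand_groups(traj: Trajectory, ligand_selection) -> list[np.ndarray]:
    """Split a ligand selection into per-molecule atom index arrays."""
    idx = resolve(ligand_selection, traj.topology)
    if idx.size == 0:
        raise ValueError("ligand selection resolves to no atoms")
    top = traj.topology
    keys = [(top.chain_ids[i], top.residue_ids[i]) for i in idx]
    order: dict[tuple, list[int]] = {}
    for i, k in zip(idx, keys):
        order.setdefault(k, []).append(int(i))
    return [np.array(v) for v in order.values()]


def _atoms_by_name(traj: Trajectory, group: np.ndarray, names) -> dict[str, int]:
    found = {}
    top = traj.topology
    for i in group:
        if top.names[i] in names:
            found[top.names[i]] = int(i)
    return found


def order_parameters(
    traj: Trajectory,
    schema: LigandSchema,
    normal=(0.0, 0.0, 1.0),
    ligand_selection: Selection | str = "role:ligand",
    allow_vector_fallback: bool = False,
) -> OrderParameterProfile:
    """Per-carbon deuterium order parameter profile.

    Requires the hydrogens named in ``schema.ch_pairs``; with
    ``allow_vector_fallback`` carbons lacking hydrogens use the
    C(i−1)→C(i+1) axis as the orientation vector instead (flagged on the
    returned profile).
    """
    normal = np.asarray(normal, dtype=np.float64)
    normal /= np.linalg.norm(normal)
    groups = _ligand_groups(traj, ligand_selection)
    carbons = list(schema.tail_atoms)
    sums = np.zeros(len(carbons))
    sq_sums = np.zeros(len(carbons))
    counts = np.zeros(len(carbons))
    used_fallback = False

    for group in groups:
        names_needed = set(carbons)
        for hs in schema.ch_pairs.values():
            names_needed |= set(hs)
        name_to_idx = _atoms_by_name(traj, group, names_needed)
        for ci, cname in enumerate(carbons):
            if cname not in name_to_idx:
                raise ValueError(f"tail carbon {cname!r} missing from a ligand")
            c_idx = name_to_idx[cname]
            h_names = [h for h in schema.ch_pairs.get(cname, ()) if h in name_to_idx]
            if h_names:
                vecs = [
                    traj.xyz[:, name_to_idx[h]] - traj.xyz[:, c_idx] for h in h_names
                ]
            elif allow_vector_fallback:
                used_fallback = True
                pos = carbons.index(cname)
                prev = carbons[pos - 1] if pos > 0 else None
                nxt = carbons[pos + 1] if pos + 1 < len(carbons) else None
                if prev is None or nxt is None or prev not in name_to_idx or nxt not in name_to_idx:
                    continue
                vecs = [traj.xyz[:, name_to_idx[nxt]] - traj.xyz[:, name_to_idx[prev]]]
            else:
                raise ValueError(
                    f"no hydrogens found for carbon {cname!r}; add them to the "
                    "topology or enable allow_vector_fallback"
                )
            for v in vecs:
                cos = (v @ normal) / np.linalg.norm(v, axis=1)
                s = 1.5 * cos**2 - 0.5
                sums[ci] += s.sum()
                sq_sums[ci] += (s**2).sum()
                counts[ci] += s.size

    mean = sums / np.maximum(counts, 1)
    var = np.maximum(sq_sums / np.maximum(counts, 1) - mean**2, 0.0)
    stderr = np.sqrt(var / np.maximum(counts, 1))
    return OrderParameterProfile(
        carbons=carbons,
        s_cd=mean,
        stderr=stderr,
        n_samples=counts.astype(int),
        used_hydrogen_fallback=used_fallback,
    )


def radius_of_gyration(
    traj: Trajectory,
    schema: LigandSchema,
    ligand_selection: Selection | str = "role:ligand",
) -> ChainShapeSeries:
    """Unweighted tail-carbon radius of gyration per ligand per frame:
    Rg² is the mean squared distance to the tail centroid."""
    groups = _ligand_groups(traj, ligand_selection)
    tail_set = set(schema.tail_atoms)
    cols = []
    for group in groups:
        tail_idx = np.array(
            [i for i in group if traj.topology.names[i] in tail_set]
        )
        if tail_idx.size == 0:
            raise ValueError("a ligand has no tail carbons from the schema")
        pos = traj.xyz[:, tail_idx]  # (F, n_tail, 3)
        centroid = pos.mean(axis=1, keepdims=True)
        rg = np.sqrt(np.mean(np.sum((pos - centroid) ** 2, axis=2), axis=1))
        cols.append(rg)
    return ChainShapeSeries(
        times_ns=traj.times.copy(),
        values=np.column_stack(cols),
        quantity="radius_of_gyration_A",
    )


def head_to_tail_distance(
    traj: Trajectory,
    schema: LigandSchema,
    ligand_selection: Selection | str = "role:ligand",
) -> ChainShapeSeries:
    """Minimum-image distance from the designated head oxygen to the
    terminal tail carbon, per ligand per frame."""
    groups = _ligand_groups(traj, ligand_selection)
    cols = []
    for group in groups:
        by_name = _atoms_by_name(
            traj, group, {schema.head_oxygen, schema.terminal_carbon}
        )
        if schema.head_oxygen not in by_name:
            raise ValueError(
                f"designated head oxygen {schema.head_oxygen!r} missing from a ligand"
            )
        if schema.terminal_carbon not in by_name:
            raise ValueError(
                f"terminal carbon {schema.terminal_carbon!r} missing from a ligand"
            )
        o = traj.xyz[:, by_name[schema.head_oxygen]]
        c = traj.xyz[:, by_name[schema.terminal_carbon]]
        cols.append(minimum_image_distance(o, c, traj.boxes))
    return ChainShapeSeries(
        times_ns=traj.times.copy(),
        values=np.column_stack(cols),
        quantity="head_to_tail_distance_A",
    )
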