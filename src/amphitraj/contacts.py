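"""Residue-level contact analysis against ligand head/tail parts.

A protein residue is *in contact* with ligand part p (head or tail) at a
frame iff the minimum over (residue atom, part atom) minimum-image distances
is within the cutoff (default 3.5 Å).  Contacts are accumulated over time
and filtered by a persistence threshold (default: cumulative contact time
strictly greater than 300 ns); both the raw and the filtered tables are
kept.  All ligand copies are pooled per part — any copy's head counts as a
head contact — matching how a many-ligand system is normally fingerprinted;
per-ligand resolution is available via ``per_ligand=True``.

Neighbor search uses a periodic KD-tree whose result is defined to equal the
brute-force all-pairs computation (property-tested against it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Topology, Trajectory, residue_class
from .schema import LigandSchema
from .selection import Selection, resolve

__all__ = [
    "ContactCriterion",
    "ContactEvents",
    "ContactTable",
    "RegionSummary",
    "detect_contacts",
    "contact_table",
    "region_summary",
    "proximity_count",
]


@dataclass
class ContactCriterion:
    distance_cutoff: float = 3.5  # Å
    persistence_threshold: float = 300.0  # ns, strict "more than"
    persistence_mode: str = "cumulative"  # or "longest_continuous"
    atom_policy: str = "heavy"  # or "all"

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be > 0")
        if self.persistence_threshold < 0:
            raise ValueError("persistence_threshold must be >= 0")
        if self.persistence_mode not in ("cumulative", "longest_continuous"):
            raise ValueError(f"unknown persistence_mode {self.persistence_mode!r}")
        if self.atom_policy not in ("heavy", "all"):
            raise ValueError(f"unknown atom_policy {self.atom_policy!r}")


@dataclass
class ContactEvents:
    """Per-frame boolean contact events, residue × ligand part."""

    residues: list[tuple[str, int, str]]  # (chain_id, residue_id, residue_name)
    parts: list[str]
    events: np.ndarray  # (n_frames, n_residues, n_parts) bool
    times_ns: np.ndarray
    criterion: ContactCriterion


def _check_cutoff(cutoff: float, boxes: np.ndarray) -> None:
    half_min = float(boxes.min()) / 2.0
    if cutoff > half_min:
        raise ValueError(
            f"cutoff {cutoff} Å exceeds half the smallest box edge "
            f"({half_min:.2f} Å): minimum-image distances become ambiguous"
        )


def _part_atoms(
    top: Topology, ligand_idx: np.ndarray, schema: LigandSchema, policy: str
) -> dict[str, np.ndarray]:
    heavy = top.heavy_mask()
    out = {}
    for part, names in (("head", schema.head_atoms), ("tail", set(schema.tail_atoms))):
        sel = [
            int(i)
            for i in ligand_idx
            if top.names[i] in names and (policy == "all" or heavy[i])
        ]
        out[part] = np.array(sel, dtype=np.int64)
    return out


def _pairs_within(
    a_pos: np.ndarray, b_pos: np.ndarray, box: np.ndarray, cutoff: float
):
    """Indices (i, j) with minimum-image |a_i − b_j| ≤ cutoff, via periodic
    KD-tree."""
    a = np.mod(a_pos, box)
    b = np.mod(b_pos, box)
    # guard against coordinates landing exactly on the upper box face
    a = np.where(a >= box, 0.0, a)
    b = np.where(b >= box, 0.0, b)
    tree_b = cKDTree(b, boxsize=box)
    hits = cKDTree(a, boxsize=box).query_ball_tree(tree_b, r=cutoff)
    return hits  # list over a-index → list of b-indices


def detect_contacts(
    traj: Trajectory,
    criterion: ContactCriterion,
    protein_selection: Selection | str,
    ligand_schema: LigandSchema,
    ligand_selection: Selection | str = "role:ligand",
    per_ligand: bool = False,
) -> ContactEvents:
    """Per-frame residue × ligand-part contact events.

    With ``per_ligand=True`` the "parts" axis becomes ``head@<resid>`` /
    ``tail@<resid>`` per ligand copy instead of pooling copies.
    """
    top = traj.topology
    _check_cutoff(criterion.distance_cutoff, traj.boxes)
    prot_idx = resolve(protein_selection, top)
    lig_idx = resolve(ligand_selection, top)
    if prot_idx.size == 0 or lig_idx.size == 0:
        raise ValueError("protein and ligand selections must be non-empty")
    if criterion.atom_policy == "heavy":
        heavy = top.heavy_mask()
        prot_idx = prot_idx[heavy[prot_idx]]

    res_keys: list[tuple[str, int, str]] = []
    res_of_atom = np.empty(prot_idx.size, dtype=np.int64)
    seen: dict[tuple[str, int], int] = {}
    for n, i in enumerate(prot_idx):
        key = (top.chain_ids[i], int(top.residue_ids[i]))
        if key not in seen:
            seen[key] = len(res_keys)
            res_keys.append((key[0], key[1], top.residue_names[i]))
        res_of_atom[n] = seen[key]

    part_map = _part_atoms(top, lig_idx, ligand_schema, criterion.atom_policy)
    if per_ligand:
        groups: dict[str, np.ndarray] = {}
        for part, idx in part_map.items():
            for i in idx:
                lig_key = f"{part}@{top.chain_ids[i]}:{top.residue_ids[i]}"
                groups.setdefault(lig_key, [])
                groups[lig_key].append(int(i))
        part_map = {k: np.array(v) for k, v in sorted(groups.items())}
    parts = list(part_map)

    events = np.zeros((traj.n_frames, len(res_keys), len(parts)), dtype=bool)
    for fi in range(traj.n_frames):
        box = traj.boxes[fi]
        prot_pos = traj.xyz[fi, prot_idx]
        for pi, part in enumerate(parts):
            pidx = part_map[part]
            if pidx.size == 0:
                continue
            hits = _pairs_within(
                prot_pos, traj.xyz[fi, pidx], box, criterion.distance_cutoff
            )
            touched = {int(res_of_atom[ai]) for ai, js in enumerate(hits) if js}
            for r in touched:
                events[fi, r, pi] = True
    return ContactEvents(
        residues=res_keys,
        parts=parts,
        events=events,
        times_ns=traj.times.copy(),
        criterion=criterion,
    )


@dataclass
class ContactTable:
    raw: pd.DataFrame
    criterion: ContactCriterion
    total_time_ns: float

    @property
    def filtered(self) -> pd.DataFrame:
        """Rows whose persistence measure is strictly greater than the
        threshold ("more than" semantics: exactly at threshold is out)."""
        measure = (
            self.raw["cumulative_ns"]
            if self.criterion.persistence_mode == "cumulative"
            else self.raw["longest_continuous_ns"]
        )
        return self.raw[measure > self.criterion.persistence_threshold].reset_index(
            drop=True
        )


def contact_table(events: ContactEvents, traj: Trajectory) -> ContactTable:
    """Accumulate events into per-(residue, part) cumulative times and
    frequencies, annotated with region, extracellular flag, and residue
    chemical class."""
    durations = traj.frame_durations()
    total = float(durations.sum())
    top = traj.topology
    rows = []
    for ri, (chain, resid, resname) in enumerate(events.residues):
        for pi, part in enumerate(events.parts):
            mask = events.events[:, ri, pi]
            cum = float(durations[mask].sum())
            if cum == 0.0:
                continue
            longest = _longest_run_ns(mask, durations)
            rows.append(
                {
                    "chain_id": chain,
                    "residue_id": resid,
                    "residue_name": resname,
                    "ligand_part": part,
                    "cumulative_ns": cum,
                    "longest_continuous_ns": longest,
                    "frequency": cum / total if total > 0 else 0.0,
                    "region": top.region_of(chain, resid),
                    "extracellular": top.is_extracellular(chain, resid),
                    "residue_class": residue_class(resname),
                }
            )
    raw = pd.DataFrame(
        rows,
        columns=[
            "chain_id", "residue_id", "residue_name", "ligand_part",
            "cumulative_ns", "longest_continuous_ns", "frequency", "region",
            "extracellular", "residue_class",
        ],
    )
    return ContactTable(raw=raw, criterion=events.criterion, total_time_ns=total)


def _longest_run_ns(mask: np.ndarray, durations: np.ndarray) -> float:
    best = cur = 0.0
    for m, d in zip(mask, durations):
        if m:
            cur += d
            best = max(best, cur)
        else:
            cur = 0.0
    return float(best)


@dataclass
class RegionSummary:
    per_part: pd.DataFrame  # part × region counts and fractions
    class_counts: pd.DataFrame
    tail_head_ratio: float | None
    fraction_s3_s4: dict[str, float | None]
    fraction_extracellular_s3_s4: dict[str, float | None]
    counts: dict[str, int]


def region_summary(table: ContactTable, topology: Topology) -> RegionSummary:
    """Region- and chemistry-level roll-up of the filtered contact table.

    ``fraction_s3_s4`` is, per part, the fraction of qualifying residue rows
    on helices S3/S4; the extracellular variant additionally requires the
    residue to lie on the extracellular half."""
    df = table.filtered
    parts = sorted(df["ligand_part"].unique()) if len(df) else []
    region_rows = []
    counts: dict[str, int] = {}
    frac_s34: dict[str, float | None] = {}
    frac_ec_s34: dict[str, float | None] = {}
    for part in parts:
        sub = df[df["ligand_part"] == part]
        n = len(sub)
        counts[part] = n
        for region, cnt in sub.groupby("region").size().items():
            region_rows.append(
                {"ligand_part": part, "region": region, "count": int(cnt),
                 "fraction": cnt / n}
            )
        on_s34 = sub["region"].isin(["S3", "S4"])
        frac_s34[part] = float(on_s34.mean()) if n else None
        frac_ec_s34[part] = float((on_s34 & sub["extracellular"]).mean()) if n else None
    per_part = pd.DataFrame(
        region_rows, columns=["ligand_part", "region", "count", "fraction"]
    )
    class_counts = (
        df.groupby(["ligand_part", "residue_class"]).size().rename("count").reset_index()
        if len(df)
        else pd.DataFrame(columns=["ligand_part", "residue_class", "count"])
    )
    n_head, n_tail = counts.get("head", 0), counts.get("tail", 0)
    ratio = (n_tail / n_head) if n_head else None
    return RegionSummary(
        per_part=per_part,
        class_counts=class_counts,
        tail_head_ratio=ratio,
        fraction_s3_s4=frac_s34,
        fraction_extracellular_s3_s4=frac_ec_s34,
        counts=counts,
    )


def proximity_count(
    traj: Trajectory,
    target_selection: Selection | str,
    probe_selection: Selection | str,
    cutoff: float,
    group_by_molecule: bool = False,
) -> np.ndarray:
    """Number of probe entities within ``cutoff`` of the target, per frame.

    Entities are single atoms by default, or whole molecules (any atom
    within cutoff ⇒ the molecule counts once) with ``group_by_molecule``.
    Atoms present in both selections are never counted as their own
    neighbours.
    """
    top = traj.topology
    _check_cutoff(cutoff, traj.boxes)
    t_idx = resolve(target_selection, top)
    p_idx = resolve(probe_selection, top)
    if t_idx.size == 0 or p_idx.size == 0:
        raise ValueError("target and probe selections must be non-empty")
    t_set = set(t_idx.tolist())
    if group_by_molecule:
        mol_keys = [(top.chain_ids[i], int(top.residue_ids[i])) for i in p_idx]
        uniq = sorted(set(mol_keys))
        mol_of = np.array([uniq.index(k) for k in mol_keys])
        n_mol = len(uniq)
    counts = np.zeros(traj.n_frames, dtype=np.int64)
    for fi in range(traj.n_frames):
        hits = _pairs_within(
            traj.xyz[fi, p_idx], traj.xyz[fi, t_idx], traj.boxes[fi], cutoff
        )
        near = np.zeros(p_idx.size, dtype=bool)
        for ai, js in enumerate(hits):
            # exclude self-pairing when an atom appears in both selections
            global_js = [int(t_idx[j]) for j in js]
            if any(g != int(p_idx[ai]) for g in global_js):
                near[ai] = True
            elif global_js and int(p_idx[ai]) not in t_set:
                near[ai] = True
        if group_by_molecule:
            counts[fi] = int(np.unique(mol_of[near]).size)
        else:
            counts[fi] = int(near.sum())
    return counts
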