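"""Segment-wise minimum-distance profiles, residence-time analysis, and
backbone RMSD against the trajectory-average structure.

Minimum distances are reported per protein subunit and per ligand segment
(five-part HEAD/TAIL-A..D sectioning, or the coarser head vs C12-terminal
tail split used to discriminate head from tail near designated residues);
the cross-subunit standard error uses the subunit time-means as the n
samples, matching the "error bars are the SE across the four subunits"
convention.

Residency treats a probe molecule as resident while *any* of its atoms lies
within the cutoff (default 2 Å) of the target; continuous intervals are
computed on the frame grid with an optional gap tolerance that bridges
interruptions of at most g frames.

RMSD uses a two-pass procedure: superpose every frame onto the first,
average the superposed coordinates, then superpose each original frame onto
that average structure (unweighted least-squares/Kabsch) and report the
RMSD.  The series is invariant to rigid motion of any frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Trajectory, minimum_image_displacement
from .schema import LigandSchema
from .selection import Selection, resolve

__all__ = [
    "SegmentDistanceProfile",
    "ResidencyRecord",
    "RmsdSeries",
    "segment_min_distances",
    "residency",
    "backbone_rmsd",
    "kabsch_rotation",
]


@dataclass
class SegmentDistanceProfile:
    subunits: list[str]
    segments: list[str]
    times_ns: np.ndarray
    distances: np.ndarray  # (n_frames, n_subunits, n_segments)
    segmentation: str

    def subunit_means(self) -> np.ndarray:
        """Time-mean per (subunit, segment)."""
        return self.distances.mean(axis=0)

    def summary(self) -> pd.DataFrame:
        """Cross-subunit mean and standard error per segment (n = number of
        subunits)."""
        per_sub = self.subunit_means()  # (n_sub, n_seg)
        n = per_sub.shape[0]
        mean = per_sub.mean(axis=0)
        se = (
            per_sub.std(axis=0, ddof=1) / np.sqrt(n)
            if n > 1
            else np.zeros(per_sub.shape[1])
        )
        return pd.DataFrame(
            {"segment": self.segments, "mean_A": mean, "stderr_A": se, "n_subunits": n}
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for si, sub in enumerate(self.subunits):
            for gi, seg in enumerate(self.segments):
                rows.append(
                    pd.DataFrame(
                        {
                            "time_ns": self.times_ns,
                            "subunit": sub,
                            "segment": seg,
                            "min_distance_A": self.distances[:, si, gi],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def _min_image_cdist_min(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Min over all (a, b) pairs of minimum-image distances."""
    d = minimum_image_displacement(a[:, None, :], b[None, :, :], box)
    return float(np.sqrt((d * d).sum(axis=-1)).min())


def segment_min_distances(
    traj: Trajectory,
    schema: LigandSchema,
    protein_selection: Selection | str,
    ligand_selection: Selection | str = "role:ligand",
    segmentation: str = "five_part",
    heavy_only: bool = True,
) -> SegmentDistanceProfile:
    """Per-frame, per-subunit minimum distance from the selected protein
    atoms of each subunit to each ligand segment (pooled over all ligand
    copies).

    ``segmentation``: ``five_part`` uses the schema's named segments;
    ``head_tail12_22`` uses head atoms vs the schema's analysis tail.
    """
    top = traj.topology
    prot_idx = resolve(protein_selection, top)
    lig_idx = resolve(ligand_selection, top)
    if prot_idx.size == 0 or lig_idx.size == 0:
        raise ValueError("protein and ligand selections must be non-empty")
    selected_subunits = sorted({top.chain_ids[i] for i in prot_idx})
    if heavy_only:
        heavy = top.heavy_mask()
        prot_idx = prot_idx[heavy[prot_idx]]
        lig_idx = lig_idx[heavy[lig_idx]]
        remaining = {top.chain_ids[i] for i in prot_idx}
        for s in selected_subunits:
            if s not in remaining:
                raise ValueError(
                    f"subunit {s!r} has an empty target selection "
                    "(no heavy atoms remain)"
                )

    if segmentation == "five_part":
        if not schema.segments:
            raise ValueError("schema defines no named segments")
        seg_names = sorted(schema.segments, key=lambda s: (s != "HEAD", s))
        seg_atoms = {s: schema.segments[s] for s in seg_names}
    elif segmentation == "head_tail12_22":
        seg_names = ["head", "analysis_tail"]
        seg_atoms = {"head": schema.head_atoms, "analysis_tail": schema.analysis_tail}
    else:
        raise ValueError(f"unknown segmentation {segmentation!r}")

    subunits = sorted({top.chain_ids[i] for i in prot_idx})
    sub_idx = {
        s: np.array([i for i in prot_idx if top.chain_ids[i] == s]) for s in subunits
    }
    for s, idx in sub_idx.items():
        if idx.size == 0:
            raise ValueError(f"subunit {s!r} has an empty target selection")
    seg_idx = {
        name: np.array([i for i in lig_idx if top.names[i] in atoms])
        for name, atoms in seg_atoms.items()
    }
    for name, idx in seg_idx.items():
        if idx.size == 0:
            raise ValueError(f"segment {name!r} resolves to no ligand atoms")

    out = np.empty((traj.n_frames, len(subunits), len(seg_names)))
    for fi in range(traj.n_frames):
        box = traj.boxes[fi]
        for si, sub in enumerate(subunits):
            a = traj.xyz[fi, sub_idx[sub]]
            for gi, seg in enumerate(seg_names):
                out[fi, si, gi] = _min_image_cdist_min(
                    a, traj.xyz[fi, seg_idx[seg]], box
                )
    return SegmentDistanceProfile(
        subunits=subunits,
        segments=seg_names,
        times_ns=traj.times.copy(),
        distances=out,
        segmentation=segmentation,
    )


@dataclass
class ResidencyRecord:
    molecules: list[tuple[str, int]]
    intervals: dict[tuple[str, int], list[tuple[float, float]]]
    counts: np.ndarray  # per-frame number of resident molecules
    times_ns: np.ndarray
    cutoff: float
    gap_frames: int

    def interval_table(self) -> pd.DataFrame:
        rows = [
            {
                "chain_id": c,
                "residue_id": r,
                "start_ns": a,
                "end_ns": b,
                "duration_ns": b - a,
            }
            for (c, r), ivs in self.intervals.items()
            for a, b in ivs
        ]
        return pd.DataFrame(
            rows, columns=["chain_id", "residue_id", "start_ns", "end_ns", "duration_ns"]
        )


def residency(
    traj: Trajectory,
    target_selection: Selection | str,
    probe_selection: Selection | str,
    cutoff: float = 2.0,
    gap_frames: int = 0,
    site_residues: list[tuple[str, int]] | None = None,
) -> ResidencyRecord:
    """Continuous residence intervals of whole probe molecules near a target.

    ``site_residues`` restricts the target to the listed ``(chain_id,
    residue_id)`` residues (site-local residency).  Interval duration is the
    number of resident frames times the frame duration; a gap tolerance of g
    frames merges interruptions of at most g frames.
    """
    top = traj.topology
    if cutoff >= float(traj.boxes.min()) / 2.0:
        raise ValueError("cutoff must be below half the smallest box edge")
    t_idx = resolve(target_selection, top)
    if site_residues is not None:
        wanted = {(str(c), int(r)) for c, r in site_residues}
        t_idx = np.array(
            [i for i in t_idx if (top.chain_ids[i], int(top.residue_ids[i])) in wanted]
        )
    p_idx = resolve(probe_selection, top)
    if t_idx.size == 0 or p_idx.size == 0:
        raise ValueError("target and probe selections must be non-empty")

    mol_keys = [(top.chain_ids[i], int(top.residue_ids[i])) for i in p_idx]
    molecules = sorted(set(mol_keys))
    mol_of = np.array([molecules.index(k) for k in mol_keys])

    resident = np.zeros((traj.n_frames, len(molecules)), dtype=bool)
    from .contacts import _pairs_within

    for fi in range(traj.n_frames):
        hits = _pairs_within(
            traj.xyz[fi, p_idx], traj.xyz[fi, t_idx], traj.boxes[fi], cutoff
        )
        near = np.array([bool(js) for js in hits])
        if near.any():
            resident[fi, np.unique(mol_of[near])] = True

    durations = traj.frame_durations()
    times = traj.times
    intervals: dict[tuple[str, int], list[tuple[float, float]]] = {}
    for mi, key in enumerate(molecules):
        mask = resident[:, mi].copy()
        if gap_frames > 0:
            mask = _bridge_gaps(mask, gap_frames)
        ivs = []
        start = None
        for fi in range(len(mask)):
            if mask[fi] and start is None:
                start = fi
            if start is not None and (fi == len(mask) - 1 or not mask[fi + 1]):
                if mask[fi]:
                    dur = float(durations[start : fi + 1].sum())
                    ivs.append((float(times[start]), float(times[start]) + dur))
                    start = None
        intervals[key] = ivs
        resident[:, mi] = mask
    return ResidencyRecord(
        molecules=molecules,
        intervals=intervals,
        counts=resident.sum(axis=1).astype(np.int64),
        times_ns=times.copy(),
        cutoff=cutoff,
        gap_frames=gap_frames,
    )


def _bridge_gaps(mask: np.ndarray, g: int) -> np.ndarray:
    out = mask.copy()
    idx = np.flatnonzero(mask)
    for a, b in zip(idx[:-1], idx[1:]):
        if 1 < b - a <= g + 1:
            out[a:b] = True
    return out


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation (least-squares, proper) aligning centred P onto
    centred Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


@dataclass
class RmsdSeries:
    times_ns: np.ndarray
    rmsd_A: np.ndarray
    average_structure: np.ndarray  # (n_atoms, 3), centred
    n_atoms: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times_ns, "rmsd_A": self.rmsd_A})


def backbone_rmsd(
    traj: Trajectory,
    protein_selection: Selection | str = "role:protein and name:CA",
) -> RmsdSeries:
    """Backbone RMSD of each frame against the trajectory-average structure
    after optimal superposition (two-pass procedure)."""
    idx = resolve(protein_selection, traj.topology)
    if idx.size < 3:
        raise ValueError("need at least 3 atoms for superposition")
    coords = traj.xyz[:, idx]  # (F, N, 3)
    centred = coords - coords.mean(axis=1, keepdims=True)
    spread = np.linalg.svd(centred[0], compute_uv=False)
    if spread[1] < 1e-8:
        raise ValueError("selection geometry is collinear; superposition is degenerate")

    # pass 1: superpose all frames onto frame 0, average
    ref = centred[0]
    aligned = np.empty_like(centred)
    for fi in range(centred.shape[0]):
        R = kabsch_rotation(centred[fi], ref)
        aligned[fi] = centred[fi] @ R.T
    avg = aligned.mean(axis=0)
    avg = avg - avg.mean(axis=0)

    # pass 2: superpose each frame onto the average structure
    rmsd = np.empty(centred.shape[0])
    for fi in range(centred.shape[0]):
        R = kabsch_rotation(centred[fi], avg)
        diff = centred[fi] @ R.T - avg
        rmsd[fi] = np.sqrt(np.mean(np.sum(diff**2, axis=1)))
    return RmsdSeries(
        times_ns=traj.times.copy(),
        rmsd_A=rmsd,
        average_structure=avg,
        n_atoms=int(idx.size),
    )
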