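"""Occupancy density grids, iso-surface export, and lateral diffusion.

An occupancy grid voxelises the fraction of frames in which at least one
selected atom lies inside each voxel; "X % occupancy" iso-surfaces are level
sets of that fraction.  Frames can be superposed on a protein selection
before binning so the map lives in the protein-centred frame.

Lateral diffusion follows the standard 2-D Einstein route: per-molecule
centre-of-geometry (x, y) tracks are unwrapped across the periodic box,
optionally re-expressed relative to a reference (protein) centre, combined
into a time- and ensemble-averaged MSD with overlapping origins, and fitted
by least squares over a configurable lag window; D = slope / 4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Trajectory
from .distres import kabsch_rotation
from .selection import Selection, resolve

__all__ = [
    "OccupancyGrid",
    "LateralTrack",
    "DiffusionResult",
    "occupancy_grid",
    "iso_surface_export",
    "write_opendx",
    "lateral_diffusion",
    "unwrap_coordinates",
    "msd_fft",
]

A2NS_TO_CM2S = 1e-7  # 1 Å²/ns = 1e-16 cm² / 1e-9 s


@dataclass
class OccupancyGrid:
    origin: np.ndarray  # (3,) Å
    voxel: float  # Å edge
    occupancy: np.ndarray  # (nx, ny, nz) fraction of frames in [0, 1]
    n_frames: int
    selection: str = ""
    aligned_to: str | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    def voxels_above(self, threshold: float) -> int:
        return int(np.count_nonzero(self.occupancy > threshold))


def occupancy_grid(
    traj: Trajectory,
    selection: Selection | str,
    voxel: float = 1.0,
    align_to: Selection | str | None = None,
    margin: float = 2.0,
) -> OccupancyGrid:
    """Fractional-occupancy voxel grid for a selection.

    With ``align_to`` every frame is first rigid-body superposed onto frame 0
    of that (typically protein backbone) selection, so the density is
    accumulated in the protein-centred frame.
    """
    if voxel <= 0:
        raise ValueError("voxel edge must be > 0")
    idx = resolve(selection, traj.topology)
    if idx.size == 0:
        raise ValueError("selection resolves to no atoms")

    coords = traj.xyz[:, idx].copy()  # (F, N, 3)
    if align_to is not None:
        a_idx = resolve(align_to, traj.topology)
        if a_idx.size < 3:
            raise ValueError("align_to selection needs at least 3 atoms")
        ref = traj.xyz[0, a_idx]
        ref_c = ref.mean(axis=0)
        for fi in range(traj.n_frames):
            mob = traj.xyz[fi, a_idx]
            mob_c = mob.mean(axis=0)
            R = kabsch_rotation(mob - mob_c, ref - ref_c)
            coords[fi] = (coords[fi] - mob_c) @ R.T + ref_c

    lo = coords.reshape(-1, 3).min(axis=0) - margin
    hi = coords.reshape(-1, 3).max(axis=0) + margin
    dims = np.maximum(np.ceil((hi - lo) / voxel).astype(int), 1)
    counts = np.zeros(tuple(dims), dtype=np.int64)
    for fi in range(traj.n_frames):
        cells = np.floor((coords[fi] - lo) / voxel).astype(int)
        cells = np.clip(cells, 0, dims - 1)
        uniq = np.unique(cells, axis=0)
        counts[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    occ = counts / float(traj.n_frames)
    return OccupancyGrid(
        origin=lo,
        voxel=float(voxel),
        occupancy=occ,
        n_frames=traj.n_frames,
        selection=str(getattr(selection, "expression", selection)),
        aligned_to=str(getattr(align_to, "expression", align_to)) if align_to is not None else None,
    )


def write_opendx(grid: OccupancyGrid, path) -> None:
    """Write the grid as OpenDX text (readable by common molecular viewers)."""
    nx, ny, nz = grid.shape
    with open(path, "w") as fh:
        fh.write("# amphitraj occupancy grid (fraction of frames)\n")
        fh.write(f"# selection: {grid.selection}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {grid.origin[0]:.4f} {grid.origin[1]:.4f} {grid.origin[2]:.4f}\n")
        fh.write(f"delta {grid.voxel:.4f} 0 0\n")
        fh.write(f"delta 0 {grid.voxel:.4f} 0\n")
        fh.write(f"delta 0 0 {grid.voxel:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = grid.occupancy.ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6g}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def iso_surface_export(
    grid: OccupancyGrid,
    threshold: float,
    dx_path=None,
    obj_path=None,
):
    """Marching-cubes iso-surface of the occupancy grid at ``threshold``.

    Returns ``(vertices, faces, n_voxels_above)``; vertices are in Å
    (grid origin + voxel scaling).  Optionally writes the volumetric grid as
    OpenDX and the surface as Wavefront OBJ.  If no voxel exceeds the
    threshold an empty surface is returned with a warning.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    n_above = grid.voxels_above(threshold)
    if dx_path is not None:
        write_opendx(grid, dx_path)
    if n_above == 0 or grid.occupancy.max() <= threshold or grid.occupancy.min() > threshold:
        if n_above == 0:
            warnings.warn(
                f"no voxel above occupancy {threshold}; surface is empty",
                stacklevel=2,
            )
        verts = np.empty((0, 3))
        faces = np.empty((0, 3), dtype=int)
    else:
        from skimage.measure import marching_cubes

        verts, faces, _, _ = marching_cubes(grid.occupancy, level=threshold)
        verts = grid.origin + verts * grid.voxel
    if obj_path is not None:
        with open(obj_path, "w") as fh:
            fh.write("# amphitraj iso-surface\n")
            for v in verts:
                fh.write(f"v {v[0]:.4f} {v[1]:.4f} {v[2]:.4f}\n")
            for f in faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    return verts, faces, n_above


# --- lateral diffusion ---------------------------------------------------

def unwrap_coordinates(wrapped: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    """Unwrap a (F, 2) track across a periodic box: successive displacements
    are mapped to the minimum image, then re-accumulated."""
    steps = np.diff(wrapped, axis=0)
    steps -= box_xy * np.round(steps / box_xy)
    out = np.concatenate([wrapped[:1], wrapped[:1] + np.cumsum(steps, axis=0)])
    return out


def msd_fft(track: np.ndarray) -> np.ndarray:
    """Time-averaged MSD over all overlapping origins (FFT algorithm).

    ``track``: (F, d) unwrapped coordinates.  Returns MSD for lags 0..F-1.
    """
    n = track.shape[0]
    nfft = 1 << (2 * n - 1).bit_length()
    s2 = np.zeros(n)
    for dim in range(track.shape[1]):
        x = track[:, dim]
        fx = np.fft.rfft(x, nfft)
        acf = np.fft.irfft(fx * np.conj(fx), nfft)[:n]
        s2 += acf
    counts = np.arange(n, 0, -1).astype(float)
    sq = np.sum(track**2, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(sq)])
    # S1(m) = sum_{k=0}^{n-m-1} (|r_k|² + |r_{k+m}|²)
    total = cum[-1]
    s1 = np.array([cum[n - m] + (total - cum[m]) for m in range(n)])
    return (s1 - 2.0 * s2) / counts


@dataclass
class LateralTrack:
    molecule: tuple[str, int]
    xy_unwrapped: np.ndarray  # (F, 2), Å, reference-centred


@dataclass
class DiffusionResult:
    tracks: list[LateralTrack]
    lags_ns: np.ndarray
    msd_A2: np.ndarray  # ensemble-and-time-averaged
    D_A2_per_ns: float
    D_cm2_per_s: float
    stderr_A2_per_ns: float
    fit_window: tuple[float, float]
    anomalous_exponent: float
    superdiffusive_flag: bool

    def msd_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_ns": self.lags_ns, "msd_A2": self.msd_A2})


def lateral_diffusion(
    traj: Trajectory,
    molecule_selection: Selection | str = "role:ligand",
    reference_selection: Selection | str | None = None,
    fit_window: tuple[float, float] = (0.1, 0.5),
    exclude_molecules: set[tuple[str, int]] | None = None,
) -> DiffusionResult:
    """Fit the lateral (xy) diffusion constant from per-molecule MSD curves.

    ``fit_window`` is the lag range as fractions of the maximum lag;
    D = slope/4 from an unweighted least-squares line through the combined
    MSD over that window.  A log–log anomalous-diffusion exponent over the
    window serves as a curvature diagnostic (flagged when it exceeds 1.3,
    e.g. for coherent drift where MSD ∝ t²).
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for diffusion analysis")
    top = traj.topology
    idx = resolve(molecule_selection, top)
    if idx.size == 0:
        raise ValueError("molecule selection resolves to no atoms")
    keys = [(top.chain_ids[i], int(top.residue_ids[i])) for i in idx]
    molecules = sorted(set(keys))
    if exclude_molecules:
        molecules = [m for m in molecules if m not in exclude_molecules]
        if not molecules:
            raise ValueError("all molecules excluded")
    box_xy = traj.boxes[0][:2]

    ref_track = None
    if reference_selection is not None:
        r_idx = resolve(reference_selection, top)
        if r_idx.size == 0:
            raise ValueError("reference selection resolves to no atoms")
        ref_track = unwrap_coordinates(
            traj.xyz[:, r_idx, :2].mean(axis=1), box_xy
        )

    tracks = []
    msd_sum = np.zeros(traj.n_frames)
    for mol in molecules:
        m_idx = np.array([i for i, k in zip(idx, keys) if k == mol])
        cog = traj.xyz[:, m_idx, :2].mean(axis=1)
        unwrapped = unwrap_coordinates(cog, box_xy)
        if ref_track is not None:
            unwrapped = unwrapped - ref_track
        tracks.append(LateralTrack(molecule=mol, xy_unwrapped=unwrapped))
        msd_sum += msd_fft(unwrapped)
    msd = msd_sum / len(molecules)

    dt = traj.dt_ns
    lags = np.arange(traj.n_frames) * dt
    lo, hi = fit_window
    max_lag = lags[-1]
    sel = (lags >= lo * max_lag) & (lags <= hi * max_lag) & (lags > 0)
    if sel.sum() < 3:
        raise ValueError(
            f"fit window {fit_window} leaves fewer than 3 lags "
            f"({int(sel.sum())}) for the fit"
        )
    x, y = lags[sel], msd[sel]
    A = np.vstack([x, np.ones_like(x)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = float(coef[0])
    n_pts = x.size
    if n_pts > 2 and res.size:
        s2 = float(res[0]) / (n_pts - 2)
        slope_se = np.sqrt(s2 / np.sum((x - x.mean()) ** 2))
    else:
        slope_se = 0.0
    D = slope / 4.0

    pos = (y > 0) & (x > 0)
    if pos.sum() >= 3:
        alpha = float(np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)[0])
    else:
        alpha = float("nan")
    return DiffusionResult(
        tracks=tracks,
        lags_ns=lags,
        msd_A2=msd,
        D_A2_per_ns=D,
        D_cm2_per_s=D * A2NS_TO_CM2S,
        stderr_A2_per_ns=slope_se / 4.0,
        fit_window=fit_window,
        anomalous_exponent=alpha,
        superdiffusive_flag=bool(alpha > 1.3) if np.isfinite(alpha) else False,
    )
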