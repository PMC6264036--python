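"""Goal functions: FLIP image stacks as broken-P1 fields, and the misfit.

The calibration compares simulated intensity fields against a *goal function*:
the FLIP image series denoised with a 1-pixel Gaussian blur and represented
frame by frame as a piecewise-linear discontinuous field on the simulation
mesh (each triangle samples the image independently at its three vertices, so
the goal lives in exactly the same broken space as the simulation).  The
misfit is the frame-averaged squared L2 distance

    E = (1/n) * sum_i  int_Omega |c_sim(t_i) - c_goal(t_i)|^2 dx,

evaluated exactly through the DG mass matrix.

Image convention: TIFF row 0 is the top of the image; physical coordinates
put the origin at the lower-left pixel corner with y increasing upward, so
rows are flipped on import and export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import tifffile
import yaml
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.spatial import cKDTree

from .dg_core import DGSpace, assemble_mass
from .flip_model import BleachProtocol, FrameSeries
from .mesh_geometry import TriangleMesh

__all__ = [
    "ImageStack",
    "GoalSeries",
    "load_and_denoise",
    "project_frame_to_dg",
    "project_stack",
    "misfit",
    "rasterize_frame",
    "save_series_tiff",
    "load_series_tiff",
]

#: The goal series is structurally a frame series on the simulation space.
GoalSeries = FrameSeries


@dataclass
class ImageStack:
    """A FLIP image time series with physical metadata.

    ``frames``: (n, H, W) float intensities; ``pixel_size`` in um/pixel;
    ``dt_frame`` in seconds.
    """

    frames: np.ndarray
    pixel_size: float
    dt_frame: float
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("image intensities must be finite")
        if self.pixel_size <= 0 or self.dt_frame <= 0:
            raise ValueError("pixel_size and dt_frame must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".yaml")


def load_and_denoise(path, blur_radius: float = 1.0,
                     pixel_size: float | None = None,
                     dt_frame: float | None = None) -> ImageStack:
    """Read a multi-frame TIFF and denoise each frame with a Gaussian blur.

    The default blur radius is 1 pixel (the standard deviation of the
    normalized Gaussian kernel).  ``pixel_size`` and ``dt_frame`` may be given
    directly or read from a ``<file>.yaml`` sidecar written by
    :func:`save_series_tiff`.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a (n, H, W) TIFF stack, got shape {arr.shape}")
    arr = arr.astype(float)

    meta = {}
    sc = _sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            meta = yaml.safe_load(fh) or {}
    if pixel_size is None:
        pixel_size = meta.get("pixel_size")
    if dt_frame is None:
        dt_frame = meta.get("dt_frame")
    if pixel_size is None or dt_frame is None:
        raise ValueError("pixel_size and dt_frame must be provided directly or via a YAML sidecar")

    if blur_radius > 0:
        # reflective extension preserves constants and, for interior features,
        # the total intensity (the kernel is normalized)
        arr = np.stack([gaussian_filter(f, sigma=blur_radius, mode="reflect") for f in arr])
    ts = meta.get("times")
    return ImageStack(frames=arr, pixel_size=float(pixel_size), dt_frame=float(dt_frame),
                      timestamps=None if ts is None else np.asarray(ts, dtype=float))


# ---------------------------------------------------------------------------
# image <-> mesh mapping
# ---------------------------------------------------------------------------


def _phys_to_pixel(coords: np.ndarray, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Physical (x, y) um -> fractional (row, col) pixel coordinates (y flipped)."""
    H, _ = shape
    col = coords[:, 0] / pixel_size - 0.5
    row = H - 0.5 - coords[:, 1] / pixel_size
    return np.column_stack([row, col])


def project_frame_to_dg(frame: np.ndarray, mesh: TriangleMesh, pixel_size: float,
                        space: DGSpace | None = None) -> np.ndarray:
    """Sample an image frame onto the broken-P1 space by bilinear interpolation.

    Every dof takes the bilinearly interpolated image value at its vertex
    location; because each triangle samples independently, the result is
    discontinuous across edges exactly like the simulation fields.
    """
    space = space if space is not None else DGSpace(mesh)
    rc = _phys_to_pixel(space.dof_coords, frame.shape, pixel_size)
    H, W = frame.shape
    if (rc[:, 0].min() < -0.5 or rc[:, 0].max() > H - 0.5
            or rc[:, 1].min() < -0.5 or rc[:, 1].max() > W - 0.5):
        raise ValueError("a mesh dof lies outside the image extent")
    return map_coordinates(frame, rc.T, order=1, mode="nearest")


def project_stack(stack: ImageStack, mesh: TriangleMesh,
                  protocol: BleachProtocol, space: DGSpace | None = None) -> GoalSeries:
    """Project every denoised frame to the mesh at the frame comparison times."""
    space = space if space is not None else DGSpace(mesh)
    vals = np.stack([project_frame_to_dg(f, mesh, stack.pixel_size, space) for f in stack.frames])
    times = (stack.timestamps if stack.timestamps is not None
             else protocol.frame_times()[: stack.n_frames])
    return GoalSeries(times=np.asarray(times, float), values=vals)


# ---------------------------------------------------------------------------
# misfit
# ---------------------------------------------------------------------------


def misfit(sim: FrameSeries, goal: GoalSeries, mass: sp.spmatrix) -> float:
    """Frame-averaged squared L2 distance between simulation and goal."""
    if len(sim) != len(goal):
        raise ValueError(f"series lengths disagree: {len(sim)} vs {len(goal)}")
    if sim.values.shape != goal.values.shape:
        raise ValueError("series live on different spaces")
    d = sim.values - goal.values
    return float(np.einsum("ij,ij->", d, (mass @ d.T).T) / len(sim))


# ---------------------------------------------------------------------------
# rasterization (mesh field -> image) and TIFF round trip
# ---------------------------------------------------------------------------


def rasterize_frame(field: np.ndarray, mesh: TriangleMesh, pixel_size: float,
                    shape: tuple[int, int] | None = None,
                    background: float = 0.0) -> np.ndarray:
    """Evaluate a broken-P1 field at pixel centers; pixels off the mesh get background."""
    if shape is None:
        extent = mesh.vertices.max(axis=0)
        shape = (int(np.ceil(extent[1] / pixel_size)) + 1, int(np.ceil(extent[0] / pixel_size)) + 1)
    H, W = shape
    rows, cols = np.mgrid[0:H, 0:W]
    x = (cols.ravel() + 0.5) * pixel_size
    y = (H - rows.ravel() - 0.5) * pixel_size
    pts = np.column_stack([x, y])

    tri_idx = _locate(mesh, pts)
    out = np.full(len(pts), background)
    hit = tri_idx >= 0
    if hit.any():
        t = tri_idx[hit]
        bary = _barycentric(mesh, t, pts[hit])
        coeff = field.reshape(mesh.n_triangles, 3)
        out[hit] = np.einsum("ij,ij->i", bary, coeff[t])
    return out.reshape(H, W)


def _locate(mesh: TriangleMesh, pts: np.ndarray, k: int = 24) -> np.ndarray:
    """Containing triangle per point via nearest-centroid candidates (-1 if none)."""
    tree = cKDTree(mesh.centroids())
    k = min(k, mesh.n_triangles)
    _, cand = tree.query(pts, k=k)
    cand = np.atleast_2d(cand)
    res = np.full(len(pts), -1, dtype=np.int64)
    remaining = np.arange(len(pts))
    for j in range(cand.shape[1]):
        if len(remaining) == 0:
            break
        t = cand[remaining, j]
        b = _barycentric(mesh, t, pts[remaining])
        inside = np.all(b >= -1e-10, axis=1)
        res[remaining[inside]] = t[inside]
        remaining = remaining[~inside]
    return res


def _barycentric(mesh: TriangleMesh, tri_idx: np.ndarray, pts: np.ndarray) -> np.ndarray:
    p = mesh.vertices[mesh.triangles[tri_idx]]  # (m, 3, 2)
    v0 = p[:, 1] - p[:, 0]
    v1 = p[:, 2] - p[:, 0]
    v2 = pts - p[:, 0]
    den = v0[:, 0] * v1[:, 1] - v1[:, 0] * v0[:, 1]
    l1 = (v2[:, 0] * v1[:, 1] - v1[:, 0] * v2[:, 1]) / den
    l2 = (v0[:, 0] * v2[:, 1] - v2[:, 0] * v0[:, 1]) / den
    return np.column_stack([1.0 - l1 - l2, l1, l2])


def save_series_tiff(series: FrameSeries, mesh: TriangleMesh, pixel_size: float,
                     path, protocol: BleachProtocol | None = None,
                     shape: tuple[int, int] | None = None) -> None:
    """Rasterize a frame series to a float32 multi-frame TIFF with a YAML sidecar."""
    frames = np.stack(
        [rasterize_frame(v, mesh, pixel_size, shape) for v in series.values]
    ).astype(np.float32)
    tifffile.imwrite(str(path), frames)
    meta = {
        "pixel_size": float(pixel_size),
        "times": [float(t) for t in series.times],
        "units": {"pixel_size": "um/pixel", "times": "s", "intensity": "image units"},
    }
    if protocol is not None:
        meta.update(
            dt_frame=float(protocol.dt_frame), t_bleach=float(protocol.t_bleach),
            t_image=float(protocol.t_image), t_compare=float(protocol.t_compare),
            n_frames=int(protocol.n_frames),
        )
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def load_series_tiff(path, mesh: TriangleMesh, blur_radius: float = 1.0,
                     space: DGSpace | None = None) -> GoalSeries:
    """Load a stack written by :func:`save_series_tiff` back onto the mesh."""
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"sidecar {sc} not found")
    with open(sc) as fh:
        meta = yaml.safe_load(fh)
    stack = load_and_denoise(path, blur_radius=blur_radius,
                             pixel_size=meta["pixel_size"],
                             dt_frame=meta.get("dt_frame", 1.0))
    space = space if space is not None else DGSpace(mesh)
    vals = np.stack([project_frame_to_dg(f, mesh, stack.pixel_size, space) for f in stack.frames])
    return GoalSeries(times=np.asarray(meta["times"], float), values=vals)
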