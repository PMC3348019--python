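"""Probabilistic streamline tractography over a multi-fiber orientation field.

The field holds up to two fiber populations per voxel (crossing-fiber
model).  Streamlines are launched from the center of every seed-ROI
voxel and propagated by Euler stepping: at each step one population is
drawn with probability proportional to its volume fraction, perturbed by
an axially symmetric dispersion draw with concentration ``kappa``
(large ``kappa`` = tight around the mean axis, ``kappa = inf`` = no
dispersion, ``kappa = 0`` = uniform on the sphere), and sign-aligned
with the incoming direction — fiber orientations are axial, not polar.
A streamline is retained for a seed-to-target task iff it enters the
target mask; it is truncated on entry.

Reproducibility: every streamline draws from its own RNG substream
derived from ``(master seed, task key, seed-voxel index, sample index)``
so results are independent of execution order and byte-identical under
a fixed master seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

from .volume import AffineTransform, ROIRegistry

TERMINATION_REASONS = (
    "reached-target",
    "left-volume",
    "low-fraction",
    "curvature",
    "max-steps",
)

MAX_POPULATIONS = 2


class OrientationField:
    """Per-voxel fiber populations on a 3D lattice.

    Parameters
    ----------
    directions
        ``(nx, ny, nz, 2, 3)`` array of population mean axes; must be
        unit-norm wherever the matching fraction is positive.
    fractions
        ``(nx, ny, nz, 2)`` volume fractions in ``[0, 1]``, summing to
        at most 1 per voxel.
    kappas
        ``(nx, ny, nz, 2)`` angular concentration parameters (>= 0;
        ``inf`` means a delta on the mean axis).
    affine
        Voxel-to-world transform.
    """

    def __init__(
        self,
        directions: np.ndarray,
        fractions: np.ndarray,
        kappas: np.ndarray,
        affine: AffineTransform,
    ):
        directions = np.asarray(directions, dtype=float)
        fractions = np.asarray(fractions, dtype=float)
        kappas = np.asarray(kappas, dtype=float)
        if directions.ndim != 5 or directions.shape[3:] != (MAX_POPULATIONS, 3):
            raise ValueError("directions must have shape (nx, ny, nz, 2, 3)")
        if fractions.shape != directions.shape[:4]:
            raise ValueError("fractions shape mismatch")
        if kappas.shape != fractions.shape:
            raise ValueError("kappas shape mismatch")
        if fractions.min() < 0 or fractions.max() > 1:
            raise ValueError("fractions must lie in [0, 1]")
        if (fractions.sum(axis=3) > 1 + 1e-9).any():
            raise ValueError("fractions must sum to <= 1 per voxel")
        active = fractions > 0
        norms = np.linalg.norm(directions, axis=4)
        if not np.allclose(norms[active], 1.0, atol=1e-6):
            raise ValueError("active population directions must be unit-norm")
        self.directions = directions
        self.fractions = fractions
        self.kappas = kappas
        self.affine = affine

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fractions.shape[:3]  # type: ignore[return-value]

    def primary_only(self) -> "OrientationField":
        """Copy of the field with the second population removed.

        Used to contrast crossing-aware tracking against a single-fiber
        model in which the minor population of each voxel is discarded.
        """
        fr = self.fractions.copy()
        di = self.directions.copy()
        ka = self.kappas.copy()
        minor = fr[..., 1] > fr[..., 0]
        fr[minor, 0] = fr[minor, 1]
        di[minor, 0] = di[minor, 1]
        ka[minor, 0] = ka[minor, 1]
        fr[..., 1] = 0.0
        di[..., 1, :] = 0.0
        ka[..., 1] = 0.0
        return OrientationField(di, fr, ka, self.affine)

    # ---- NIfTI round trip ------------------------------------------------
    # 4D layout, 10 channels: for each of the two populations,
    # (dx, dy, dz, fraction, kappa).

    def write_nifti(self, path: str | Path) -> None:
        nx, ny, nz = self.shape
        out = np.zeros((nx, ny, nz, 10), dtype=np.float32)
        for p in range(MAX_POPULATIONS):
            out[..., 5 * p : 5 * p + 3] = self.directions[..., p, :]
            out[..., 5 * p + 3] = self.fractions[..., p]
            kap = self.kappas[..., p]
            out[..., 5 * p + 4] = np.where(np.isinf(kap), -1.0, kap)
        nib.save(nib.Nifti1Image(out, self.affine.matrix), str(path))

    @classmethod
    def read_nifti(cls, path: str | Path) -> "OrientationField":
        img = nib.load(str(path))
        raw = np.asarray(img.dataobj, dtype=float)
        if raw.ndim != 4 or raw.shape[3] != 10:
            raise ValueError("orientation field NIfTI must have 10 channels")
        nx, ny, nz = raw.shape[:3]
        di = np.zeros((nx, ny, nz, 2, 3))
        fr = np.zeros((nx, ny, nz, 2))
        ka = np.zeros((nx, ny, nz, 2))
        for p in range(MAX_POPULATIONS):
            di[..., p, :] = raw[..., 5 * p : 5 * p + 3]
            fr[..., p] = raw[..., 5 * p + 3]
            kap = raw[..., 5 * p + 4]
            ka[..., p] = np.where(kap < 0, np.inf, kap)
        return cls(di, fr, ka, AffineTransform(img.affine))


@dataclass(frozen=True)
class TrackingParams:
    """Streamline propagation parameters (units of voxels and degrees)."""

    step_size: float = 0.5
    curvature_deg: float = 80.0
    samples_per_voxel: int = 100
    max_steps: int = 2000
    min_fraction: float = 0.05
    mask_threshold: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if not 0 < self.curvature_deg <= 180:
            raise ValueError("curvature_deg must be in (0, 180]")
        if self.samples_per_voxel < 1:
            raise ValueError("samples_per_voxel must be >= 1")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if not 0 <= self.min_fraction <= 1:
            raise ValueError("min_fraction must be in [0, 1]")
        if self.mask_threshold < 1:
            raise ValueError("mask_threshold must be >= 1")


@dataclass
class Streamline:
    """Ordered continuous voxel-space points of one bidirectional track.

    ``points`` runs from the terminus of the backward half through the
    launch point to the terminus of the forward half.  The two halves
    carry their own termination reasons.
    """

    points: np.ndarray
    reason_backward: str
    reason_forward: str

    @property
    def reached_target(self) -> bool:
        return "reached-target" in (self.reason_backward, self.reason_forward)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PathwayResult:
    """Tracking outcome for one seed-ROI -> target-ROI task."""

    seed_name: str
    target_name: str
    counts: np.ndarray
    retained: int
    n_streamlines: int
    mask_threshold: int

    @property
    def mask(self) -> np.ndarray:
        return self.counts >= self.mask_threshold

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def mask_at(self, threshold: int) -> np.ndarray:
        return self.counts >= threshold


def _perturbed_axis(
    ax: float, ay: float, az: float, kappa: float, rng
) -> tuple[float, float, float]:
    """Draw a unit vector dispersed about an axis.

    Uses the closed-form inverse CDF of the von Mises-Fisher polar
    angle; the sign alignment applied by the caller makes the resulting
    distribution axial (Watson-like).
    """
    if math.isinf(kappa):
        return ax, ay, az
    u = rng.random()
    if kappa <= 0:
        w = 2.0 * u - 1.0
    else:
        w = 1.0 + math.log(u + (1.0 - u) * math.exp(-2.0 * kappa)) / kappa
        w = max(-1.0, min(1.0, w))
    s = math.sqrt(max(0.0, 1.0 - w * w))
    phi = 2.0 * math.pi * rng.random()
    # orthonormal frame around the axis
    if abs(ax) <= abs(ay) and abs(ax) <= abs(az):
        bx, by, bz = 0.0, -az, ay
    elif abs(ay) <= abs(az):
        bx, by, bz = -az, 0.0, ax
    else:
        bx, by, bz = -ay, ax, 0.0
    nb = math.sqrt(bx * bx + by * by + bz * bz)
    bx, by, bz = bx / nb, by / nb, bz / nb
    cx = ay * bz - az * by
    cy = az * bx - ax * bz
    cz = ax * by - ay * bx
    cphi, sphi = math.cos(phi), math.sin(phi)
    return (
        w * ax + s * (cphi * bx + sphi * cx),
        w * ay + s * (cphi * by + sphi * cy),
        w * az + s * (cphi * bz + sphi * cz),
    )


def sample_step_direction(
    field: OrientationField,
    voxel: Sequence[int],
    incoming: Sequence[float] | None,
    rng,
    min_fraction: float = 0.05,
    curvature_deg: float = 80.0,
) -> tuple[tuple[float, float, float] | None, str | None]:
    """Draw one propagation direction at a voxel.

    Population choice: with no incoming direction (seeding) an eligible
    population is drawn with probability proportional to its volume
    fraction; during propagation the eligible population most parallel
    to the incoming direction is followed, which is what lets
    streamlines transit crossing-fiber regions instead of scattering.

    Returns ``(direction, None)`` on success or ``(None, reason)`` on a
    termination signal (``"low-fraction"`` when no population clears
    ``min_fraction``, ``"curvature"`` when the drawn direction bends
    more than ``curvature_deg`` away from ``incoming``).
    """
    i, j, k = voxel
    fr = field.fractions
    f0 = fr[i, j, k, 0]
    f1 = fr[i, j, k, 1]
    e0 = f0 >= min_fraction
    e1 = f1 >= min_fraction
    if not (e0 or e1):
        return None, "low-fraction"
    if e0 and e1:
        if incoming is None:
            pop = 0 if rng.random() * (f0 + f1) < f0 else 1
        else:
            d0 = field.directions[i, j, k, 0]
            d1 = field.directions[i, j, k, 1]
            ix, iy, iz = incoming
            a0 = abs(d0[0] * ix + d0[1] * iy + d0[2] * iz)
            a1 = abs(d1[0] * ix + d1[1] * iy + d1[2] * iz)
            pop = 0 if a0 >= a1 else 1
    else:
        pop = 0 if e0 else 1
    d = field.directions[i, j, k, pop]
    dx, dy, dz = _perturbed_axis(
        float(d[0]), float(d[1]), float(d[2]), float(field.kappas[i, j, k, pop]), rng
    )
    if incoming is not None:
        ix, iy, iz = incoming
        dot = dx * ix + dy * iy + dz * iz
        if dot < 0:
            dx, dy, dz, dot = -dx, -dy, -dz, -dot
        if dot < math.cos(math.radians(curvature_deg)):
            return None, "curvature"
    return (dx, dy, dz), None


def _propagate_half(
    field: OrientationField,
    start: tuple[float, float, float],
    first_dir: tuple[float, float, float],
    params: TrackingParams,
    rng,
    stop_mask: np.ndarray | None,
) -> tuple[list[tuple[float, float, float]], str]:
    """Euler-step one half of a streamline; returns (points, reason)."""
    nx, ny, nz = field.shape
    step = params.step_size
    minf = params.min_fraction
    curv = params.curvature_deg
    px, py, pz = start
    dx, dy, dz = first_dir
    pts: list[tuple[float, float, float]] = []
    for n in range(params.max_steps):
        px += dx * step
        py += dy * step
        pz += dz * step
        i, j, k = int(math.floor(px)), int(math.floor(py)), int(math.floor(pz))
        if i < 0 or j < 0 or k < 0 or i >= nx or j >= ny or k >= nz:
            return pts, "left-volume"
        pts.append((px, py, pz))
        if stop_mask is not None and stop_mask[i, j, k]:
            return pts, "reached-target"
        nxt, reason = sample_step_direction(
            field, (i, j, k), (dx, dy, dz), rng, minf, curv
        )
        if nxt is None:
            return pts, reason  # type: ignore[return-value]
        dx, dy, dz = nxt
    return pts, "max-steps"


def propagate_streamline(
    field: OrientationField,
    start: Sequence[float],
    params: TrackingParams,
    rng,
    stop_mask: np.ndarray | None = None,
) -> Streamline:
    """Track bidirectionally from a continuous voxel-space start point.

    One initial axis is drawn at the start voxel; the two halves follow
    it and its negation, and are concatenated (backward half reversed)
    into a single point list through the start point.  When
    ``stop_mask`` is given a half terminates (``reached-target``) on
    entering it and the streamline is truncated there.
    """
    sx, sy, sz = (float(c) for c in start)
    i, j, k = int(math.floor(sx)), int(math.floor(sy)), int(math.floor(sz))
    nx, ny, nz = field.shape
    if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
        raise ValueError(f"start point {start!r} outside grid {field.shape}")
    d0, reason = sample_step_direction(
        field, (i, j, k), None, rng, params.min_fraction, params.curvature_deg
    )
    if d0 is None:
        return Streamline(np.array([[sx, sy, sz]]), reason, reason)  # type: ignore[arg-type]
    fwd_pts, fwd_reason = _propagate_half(
        field, (sx, sy, sz), d0, params, rng, stop_mask
    )
    bwd_pts, bwd_reason = _propagate_half(
        field, (sx, sy, sz), (-d0[0], -d0[1], -d0[2]), params, rng, stop_mask
    )
    pts = list(reversed(bwd_pts)) + [(sx, sy, sz)] + fwd_pts
    return Streamline(np.asarray(pts, dtype=float), bwd_reason, fwd_reason)


def _substream(master_seed: int, task_key: int, voxel_idx: int, sample_idx: int):
    """Order-independent per-streamline RNG."""
    ss = np.random.SeedSequence([master_seed, task_key, voxel_idx, sample_idx])
    return random.Random(int(ss.generate_state(2, np.uint64)[0]))


def track_pathway(
    field: OrientationField,
    seed_voxels: Iterable[tuple[int, int, int]],
    target_mask: np.ndarray,
    params: TrackingParams,
    seed_name: str = "seed",
    target_name: str = "target",
    task_key: int = 0,
) -> PathwayResult:
    """Track one seed-ROI -> target-ROI task.

    ``params.samples_per_voxel`` streamlines are launched from the
    center of every seed voxel.  A streamline is retained iff it enters
    ``target_mask``; the visitation map counts, per voxel, the retained
    streamlines passing through it (each counted once per voxel).
    """
    seeds = sorted(seed_voxels)
    if not seeds:
        raise ValueError("seed voxel set is empty")
    if target_mask.shape != field.shape:
        raise ValueError("target mask shape must match field shape")
    counts = np.zeros(field.shape, dtype=np.int32)
    retained = 0
    n_total = 0
    for voxel_idx, (i, j, k) in enumerate(seeds):
        start = (i + 0.5, j + 0.5, k + 0.5)
        for sample_idx in range(params.samples_per_voxel):
            n_total += 1
            rng = _substream(params.seed, task_key, voxel_idx, sample_idx)
            sl = propagate_streamline(field, start, params, rng, target_mask)
            if not sl.reached_target:
                continue
            retained += 1
            visited = {
                (int(math.floor(x)), int(math.floor(y)), int(math.floor(z)))
                for x, y, z in sl.points
            }
            for v in visited:
                counts[v] += 1
    return PathwayResult(
        seed_name=seed_name,
        target_name=target_name,
        counts=counts,
        retained=retained,
        n_streamlines=n_total,
        mask_threshold=params.mask_threshold,
    )


def enumerate_pathway_tasks(
    registry: ROIRegistry,
    seed_structure: str,
    target_structures: Sequence[str],
) -> list[tuple[str, str]]:
    """Hemisphere-matched seed->target task list.

    The seed structure must be bilateral; each bilateral target
    contributes one task per hemisphere (left seed with left target,
    right with right).  Midline targets are excluded.
    """
    seed_entries = registry.structure_entries(seed_structure)
    if {e.hemisphere for e in seed_entries} != {"left", "right"}:
        raise ValueError(f"seed structure {seed_structure!r} is not bilateral")
    tasks: list[tuple[str, str]] = []
    for hemi in ("left", "right"):
        seed_entry = next(e for e in seed_entries if e.hemisphere == hemi)
        for tgt in target_structures:
            entries = registry.structure_entries(tgt)
            matching = [e for e in entries if e.hemisphere == hemi]
            for te in matching:
                tasks.append((seed_entry.name, te.name))
    return tasks


def write_pathway_table(results: Sequence[PathwayResult], path: str | Path) -> None:
    """Per-task TSV: seed, target, #voxels, retained streamlines."""
    import pandas as pd

    rows = [
        (r.seed_name, r.target_name, r.voxel_count, r.retained)
        for r in results
    ]
    pd.DataFrame(
        rows, columns=["seed_region", "target_region", "n_voxels", "n_retained"]
    ).to_csv(path, sep="\t", index=False)
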