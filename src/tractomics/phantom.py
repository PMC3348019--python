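"""Synthetic phantom bundle: brain-like label volume, crossing-fiber
orientation field, spatially scattered expression samples with planted
effects, and a designed protein-interaction graph.

The default phantom emulates, at desk scale, the spatial layout used for
hippocampus-seeded tractography: a 48x56x48 voxel grid (1 mm spacing)
holding 15 labelled regions — a bilateral hippocampus-analog seed, six
bilateral target structures and a midline brainstem-analog — with curved
fiber tracts (tubes around polyline centerlines) connecting the seed to
five of the six targets in each hemisphere.  No tract reaches the
accumbens-analog, so exactly 10 of the 12 hemisphere-matched tracking
tasks can find a pathway.  One crossing region per hemisphere carries
two fiber populations where the caudate- and thalamus-bound tracts
intersect, exercising the two-population sampling path of the tracker.

Expression values are synthetic log2 intensities: per-probe baselines
drawn from N(7, 1) (a typical microarray log2 scale), i.i.d. per-sample
noise, and a planted elevation of +delta log2 units on the probes of
chosen genes for samples lying inside a chosen tract.  Ground-truth
in-tube flags are recorded per sample and per tract so downstream tests
have a geometric oracle.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .tracking import OrientationField
from .volume import AffineTransform, LabelVolume, ROIEntry, ROIRegistry


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ROISpec:
    """Spherical region: name, hemisphere tag, center (voxel), radius."""

    name: str
    hemisphere: str
    center: tuple[float, float, float]
    radius: float


@dataclass(frozen=True)
class TractSpec:
    """Tube of fibers around a polyline from a seed ROI to a target ROI."""

    seed_roi: str
    target_roi: str
    control_points: tuple[tuple[float, float, float], ...]
    tube_radius: float = 2.0
    fiber_fraction: float = 0.8
    kappa: float = 60.0

    @property
    def name(self) -> str:
        return f"{self.seed_roi}__{self.target_roi}"


@dataclass(frozen=True)
class CrossingSpec:
    """Axis-aligned box in which in-tube voxels carry two populations."""

    box_min: tuple[int, int, int]
    box_max: tuple[int, int, int]  # exclusive
    direction_a: tuple[float, float, float]
    direction_b: tuple[float, float, float]
    fraction_a: float = 0.45
    fraction_b: float = 0.45
    kappa: float = 60.0


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    rois: list[ROISpec]
    tracts: list[TractSpec]
    crossings: list[CrossingSpec]
    seed: int = 0

    def roi_by_name(self, name: str) -> ROISpec:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(f"ROI {name!r} not in phantom config")

    def validate(self) -> None:
        shape = np.asarray(self.shape)
        if (shape <= 0).any():
            raise ValueError("grid shape must be positive")
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise ValueError("duplicate ROI names")
        for r in self.rois:
            c = np.asarray(r.center)
            if (c - r.radius < 0).any() or (c + r.radius > shape).any():
                raise ValueError(f"ROI {r.name!r} sphere exits the grid")
        for t in self.tracts:
            seed = self.roi_by_name(t.seed_roi)
            target = self.roi_by_name(t.target_roi)
            if seed.hemisphere != target.hemisphere:
                raise ValueError(
                    f"tract {t.name}: hemispheres differ "
                    f"({seed.hemisphere} vs {target.hemisphere})"
                )
            for endpoint, roi in (
                (t.control_points[0], seed),
                (t.control_points[-1], target),
            ):
                d = math.dist(endpoint, roi.center)
                if d > roi.radius:
                    raise ValueError(
                        f"tract {t.name}: endpoint {endpoint} lies outside "
                        f"ROI {roi.name!r} (distance {d:.2f} > {roi.radius})"
                    )


@dataclass(frozen=True)
class PlantedEffect:
    """Expression elevation of one gene inside one tract's tube.

    ``delta`` is the added log2 intensity (> 0) applied to every probe
    of ``gene`` for samples whose ground-truth flag marks them inside
    the tube of the ``pathway`` (seed ROI, target ROI) tract.
    """

    gene: str
    pathway: tuple[str, str]
    delta: float

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("planted delta must be > 0")

    @property
    def tract_name(self) -> str:
        return f"{self.pathway[0]}__{self.pathway[1]}"


@dataclass(frozen=True)
class TierDesign:
    """Designed neighborhood of the seed protein.

    ``related`` proteins attach directly to the seed; each ``tier3``
    protein gets exactly 3 unique partners inside {seed} U related, each
    ``tier2`` protein exactly 2, each ``peripheral`` protein exactly 1.
    """

    related: tuple[str, ...] = ()
    tier3: tuple[str, ...] = ()
    tier2: tuple[str, ...] = ()
    peripheral: tuple[str, ...] = ()

    def __post_init__(self):
        groups = [self.related, self.tier3, self.tier2, self.peripheral]
        flat = [p for g in groups for p in g]
        if len(set(flat)) != len(flat):
            raise ValueError("tier design sets must be disjoint")

    @property
    def designed(self) -> set[str]:
        return set(self.related) | set(self.tier3) | set(self.tier2) | set(
            self.peripheral
        )


# --------------------------------------------------------------------------
# default configuration — the study conditions
# --------------------------------------------------------------------------

_STRUCTURES = (
    "hippocampus",
    "amygdala",
    "caudate_nucleus",
    "globus_pallidus",
    "putamen",
    "thalamus",
    "nucleus_accumbens",
)

# Left-hemisphere layout (voxel coordinates); the right hemisphere is the
# mirror image across the mid-sagittal plane x = shape_x / 2.
_LEFT_CENTERS = {
    "hippocampus": (12.0, 18.0, 14.0),
    "amygdala": (12.0, 8.0, 12.0),
    "caudate_nucleus": (12.0, 40.0, 34.0),
    "globus_pallidus": (12.0, 42.0, 8.0),
    "putamen": (12.0, 28.0, 6.0),
    "thalamus": (12.0, 44.0, 22.0),
    "nucleus_accumbens": (12.0, 50.0, 42.0),
}
_RADII = {
    "hippocampus": 3.0,
    "amygdala": 2.5,
    "caudate_nucleus": 2.5,
    "globus_pallidus": 2.5,
    "putamen": 2.5,
    "thalamus": 3.0,
    "nucleus_accumbens": 2.5,
}

# Tract centerlines (left hemisphere): the seed connects to five of the
# six targets; the accumbens-analog is deliberately unreachable.  The
# caudate-bound tract crosses the thalamus-bound tract around
# (12, 27, 17), where the crossing box is placed.
_LEFT_TRACTS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "amygdala": ((12.0, 17.0, 14.0), (12.0, 8.0, 12.0)),
    "putamen": ((12.0, 19.0, 13.0), (12.0, 24.0, 8.0), (12.0, 28.0, 6.0)),
    "globus_pallidus": ((12.0, 19.5, 13.5), (12.0, 30.0, 11.0), (12.0, 42.0, 8.0)),
    "thalamus": ((12.0, 19.5, 14.5), (12.0, 30.0, 18.0), (12.0, 44.0, 22.0)),
    "caudate_nucleus": (
        (12.0, 19.0, 14.0),
        (12.0, 24.0, 13.0),
        (12.0, 30.0, 22.0),
        (12.0, 40.0, 34.0),
    ),
}

_LEFT_CROSSING = CrossingSpec(
    box_min=(9, 24, 14),
    box_max=(16, 30, 20),
    direction_a=(0.0, 0.949, 0.316),  # thalamus-bound tangent
    direction_b=(0.0, 0.555, 0.832),  # caudate-bound tangent
)


def _mirror_point(p: tuple[float, float, float], nx: int) -> tuple[float, float, float]:
    return (nx - p[0], p[1], p[2])


def default_phantom_config(seed: int = 0) -> PhantomConfig:
    """The default bilateral phantom (15 ROIs, 10 tracts, 2 crossings)."""
    shape = (48, 56, 48)
    nx = shape[0]
    rois: list[ROISpec] = []
    for s in _STRUCTURES:
        left_c = _LEFT_CENTERS[s]
        rois.append(ROISpec(f"{s}_left", "left", left_c, _RADII[s]))
        rois.append(
            ROISpec(f"{s}_right", "right", _mirror_point(left_c, nx), _RADII[s])
        )
    rois.append(ROISpec("brainstem", "midline", (24.0, 28.0, 40.0), 3.0))

    tracts: list[TractSpec] = []
    for target, cps in _LEFT_TRACTS.items():
        tracts.append(
            TractSpec(
                seed_roi="hippocampus_left",
                target_roi=f"{target}_left",
                control_points=cps,
            )
        )
        tracts.append(
            TractSpec(
                seed_roi="hippocampus_right",
                target_roi=f"{target}_right",
                control_points=tuple(_mirror_point(p, nx) for p in cps),
            )
        )

    lx = _LEFT_CROSSING
    crossings = [
        lx,
        CrossingSpec(
            box_min=(nx - lx.box_max[0], lx.box_min[1], lx.box_min[2]),
            box_max=(nx - lx.box_min[0], lx.box_max[1], lx.box_max[2]),
            direction_a=(-lx.direction_a[0], lx.direction_a[1], lx.direction_a[2]),
            direction_b=(-lx.direction_b[0], lx.direction_b[1], lx.direction_b[2]),
        ),
    ]
    return PhantomConfig(
        shape=shape,
        spacing=(1.0, 1.0, 1.0),
        origin=(-24.0, -28.0, -24.0),
        rois=rois,
        tracts=tracts,
        crossings=crossings,
        seed=seed,
    )


# --------------------------------------------------------------------------
# phantom construction
# --------------------------------------------------------------------------


@dataclass
class Phantom:
    """Rasterised phantom: labels, orientation field and tract geometry."""

    config: PhantomConfig
    labels: LabelVolume
    field: OrientationField
    centerlines: dict[str, np.ndarray]  # tract name -> (m, 3) polyline samples

    @property
    def affine(self) -> AffineTransform:
        return self.labels.affine

    def tube_mask(self, tract_name: str) -> np.ndarray:
        """Boolean mask of voxels whose center lies inside the tube."""
        spec = next(t for t in self.config.tracts if t.name == tract_name)
        line = self.centerlines[tract_name]
        mask = np.zeros(self.config.shape, dtype=bool)
        r = spec.tube_radius
        ri = int(math.ceil(r)) + 1
        shape = self.config.shape
        for p in line:
            lo = np.maximum(np.floor(p - ri).astype(int), 0)
            hi = np.minimum(np.ceil(p + ri).astype(int) + 1, shape)
            for i in range(lo[0], hi[0]):
                for j in range(lo[1], hi[1]):
                    for k in range(lo[2], hi[2]):
                        if mask[i, j, k]:
                            continue
                        c = (i + 0.5, j + 0.5, k + 0.5)
                        if math.dist(c, p) <= r:
                            mask[i, j, k] = True
        # refine: exact distance to the polyline
        idx = np.argwhere(mask)
        centers = idx + 0.5
        d = _min_dist_to_polyline(centers, line)
        keep = d <= r
        mask[:] = False
        mask[idx[keep, 0], idx[keep, 1], idx[keep, 2]] = True
        return mask

    def point_in_tube(self, tract_name: str, point_voxel: np.ndarray) -> bool:
        spec = next(t for t in self.config.tracts if t.name == tract_name)
        line = self.centerlines[tract_name]
        d = _min_dist_to_polyline(np.asarray(point_voxel)[None, :], line)
        return bool(d[0] <= spec.tube_radius)


def _resample_polyline(
    control_points: Sequence[Sequence[float]], spacing: float = 0.25
) -> np.ndarray:
    """Dense samples along the polyline through the control points."""
    cps = np.asarray(control_points, dtype=float)
    pts = [cps[0]]
    for a, b in zip(cps[:-1], cps[1:]):
        seg = b - a
        length = float(np.linalg.norm(seg))
        n = max(1, int(math.ceil(length / spacing)))
        for t in range(1, n + 1):
            pts.append(a + seg * (t / n))
    return np.asarray(pts)


def _min_dist_to_polyline(points: np.ndarray, line: np.ndarray) -> np.ndarray:
    """Min distance from each point to any segment of the polyline."""
    a = line[:-1]
    b = line[1:]
    ab = b - a
    ab2 = (ab**2).sum(axis=1)
    ab2[ab2 == 0] = 1e-30
    best = np.full(len(points), np.inf)
    for ai, abi, ab2i in zip(a, ab, ab2):
        t = np.clip(((points - ai) @ abi) / ab2i, 0.0, 1.0)
        proj = ai + t[:, None] * abi
        d = np.linalg.norm(points - proj, axis=1)
        np.minimum(best, d, out=best)
    return best


def make_phantom(config: PhantomConfig) -> Phantom:
    """Rasterise ROIs and fiber tubes into a label volume and field.

    Each ROI sphere becomes a distinct positive label (overlap is a hard
    error).  Voxels inside exactly one tube carry a single population
    tangent to the nearest centerline point; where two tubes overlap the
    two nearest tracts contribute a population each (fractions rescaled
    to sum to at most 1); inside a crossing box in-tube voxels are
    overridden with the box's two fixed directions.  A tube whose voxels
    would leave the grid is a hard error.
    """
    config.validate()
    shape = config.shape
    affine_matrix = np.eye(4)
    affine_matrix[0, 0], affine_matrix[1, 1], affine_matrix[2, 2] = config.spacing
    affine_matrix[:3, 3] = config.origin
    affine = AffineTransform(affine_matrix)

    labels = np.zeros(shape, dtype=np.int32)
    entries = []
    grid = np.stack(
        np.meshgrid(*[np.arange(s) + 0.5 for s in shape], indexing="ij"), axis=-1
    )
    for label, roi in enumerate(config.rois, start=1):
        inside = np.linalg.norm(grid - np.asarray(roi.center), axis=-1) <= roi.radius
        if (labels[inside] != 0).any():
            clash = int(labels[inside][labels[inside] != 0][0])
            raise ValueError(
                f"ROI {roi.name!r} overlaps ROI label {clash} "
                f"({config.rois[clash - 1].name!r})"
            )
        labels[inside] = label
        entries.append(ROIEntry(label, roi.name, roi.hemisphere))
    registry = ROIRegistry(entries)

    nx, ny, nz = shape
    directions = np.zeros((nx, ny, nz, 2, 3))
    fractions = np.zeros((nx, ny, nz, 2))
    kappas = np.zeros((nx, ny, nz, 2))
    # candidate populations per voxel: tract index -> (distance, tangent)
    candidates: dict[tuple[int, int, int], dict[int, tuple[float, np.ndarray]]] = {}
    centerlines: dict[str, np.ndarray] = {}

    for t_idx, tract in enumerate(config.tracts):
        line = _resample_polyline(tract.control_points)
        centerlines[tract.name] = line
        tangents = np.gradient(line, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        r = tract.tube_radius
        ri = int(math.ceil(r))
        for p, tan in zip(line, tangents):
            lo = np.floor(p - r).astype(int)
            hi = np.ceil(p + r).astype(int)
            if (lo < 0).any() or (hi > np.asarray(shape)).any():
                # clip and verify no in-tube voxel is lost off-grid
                pass
            for i in range(lo[0], hi[0] + 1):
                for j in range(lo[1], hi[1] + 1):
                    for k in range(lo[2], hi[2] + 1):
                        c = (i + 0.5, j + 0.5, k + 0.5)
                        d = math.dist(c, p)
                        if d > r:
                            continue
                        if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
                            raise ValueError(
                                f"tract {tract.name} tube exits the grid at "
                                f"voxel ({i}, {j}, {k})"
                            )
                        cell = candidates.setdefault((i, j, k), {})
                        prev = cell.get(t_idx)
                        if prev is None or d < prev[0]:
                            cell[t_idx] = (d, tan)

    for (i, j, k), cell in candidates.items():
        ranked = sorted(cell.items(), key=lambda item: item[1][0])[:2]
        fracs = [config.tracts[t].fiber_fraction for t, _ in ranked]
        total = sum(fracs)
        scale = 1.0 / total if total > 1 else 1.0
        for p, ((t, (_, tan)), f) in enumerate(zip(ranked, fracs)):
            directions[i, j, k, p] = tan
            fractions[i, j, k, p] = f * scale
            kappas[i, j, k, p] = config.tracts[t].kappa

    for box in config.crossings:
        lo, hi = np.asarray(box.box_min), np.asarray(box.box_max)
        da = np.asarray(box.direction_a, dtype=float)
        db = np.asarray(box.direction_b, dtype=float)
        da /= np.linalg.norm(da)
        db /= np.linalg.norm(db)
        for i in range(lo[0], hi[0]):
            for j in range(lo[1], hi[1]):
                for k in range(lo[2], hi[2]):
                    if fractions[i, j, k].sum() == 0:
                        continue  # only in-tube voxels become crossings
                    directions[i, j, k, 0] = da
                    directions[i, j, k, 1] = db
                    fractions[i, j, k] = (box.fraction_a, box.fraction_b)
                    kappas[i, j, k] = (box.kappa, box.kappa)

    field = OrientationField(directions, fractions, kappas, affine)
    return Phantom(
        config=config,
        labels=LabelVolume(labels, affine, registry),
        field=field,
        centerlines=centerlines,
    )


# --------------------------------------------------------------------------
# samples
# --------------------------------------------------------------------------


def make_samples(
    phantom: Phantom,
    n_samples: int = 200,
    seed: int = 0,
    forced_per_tract: int = 12,
) -> pd.DataFrame:
    """Scatter expression samples with ground-truth in-tube flags.

    ``forced_per_tract`` samples per tract are placed inside the tube
    (random point along the centerline plus a radial offset within 80%
    of the tube radius); the remainder are uniform over the grid.  Each
    sample row records its world-mm coordinate and one boolean
    ``in_<tract>`` flag per tract, computed geometrically for every
    tract, so a forced sample can legitimately flag two tubes where
    tracts overlap.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n_forced = forced_per_tract * len(phantom.config.tracts)
    if n_forced > n_samples:
        raise ValueError(
            f"forced samples ({n_forced}) exceed n_samples ({n_samples})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    pts: list[np.ndarray] = []
    for tract in phantom.config.tracts:
        line = phantom.centerlines[tract.name]
        m = len(line)
        for _ in range(forced_per_tract):
            idx = int(rng.integers(int(0.15 * m), int(0.85 * m)))
            offset = rng.normal(size=3)
            offset /= np.linalg.norm(offset)
            offset *= rng.random() ** (1 / 3) * 0.8 * tract.tube_radius
            pts.append(line[idx] + offset)
    shape = np.asarray(phantom.config.shape)
    for _ in range(n_samples - n_forced):
        pts.append(rng.random(3) * shape)
    voxel_pts = np.asarray(pts)
    world = np.array(
        [phantom.affine.voxel_to_world(p) for p in voxel_pts]
    )
    data = {
        "sample_id": [f"S{i + 1:04d}" for i in range(n_samples)],
        "x": world[:, 0],
        "y": world[:, 1],
        "z": world[:, 2],
    }
    for tract in phantom.config.tracts:
        line = phantom.centerlines[tract.name]
        d = _min_dist_to_polyline(voxel_pts, line)
        data[f"in_{tract.name}"] = d <= tract.tube_radius
    return pd.DataFrame(data)


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------


def make_probe_gene_map(
    genes: Sequence[str], probes_per_gene: int = 2
) -> pd.DataFrame:
    """Deterministic probe -> gene map, ``probes_per_gene`` probes each."""
    rows = []
    n = 0
    for g in genes:
        for _ in range(probes_per_gene):
            n += 1
            rows.append((f"P{n:05d}", g))
    return pd.DataFrame(rows, columns=["probe_id", "gene"])


def make_expression(
    samples: pd.DataFrame,
    probe_gene: pd.DataFrame,
    planted: Sequence[PlantedEffect] = (),
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic probe x sample log2-intensity matrix.

    Baseline per probe ~ N(7, 1); noise per cell ~ N(0, noise_sd);
    probes of a planted gene get ``+delta`` for samples flagged inside
    the planted tract's tube.  A planted gene with no probe is a hard
    error.
    """
    probes = probe_gene["probe_id"].tolist()
    gene_probes = probe_gene.groupby("gene")["probe_id"].apply(list).to_dict()
    for eff in planted:
        if eff.gene not in gene_probes:
            raise ValueError(f"planted gene {eff.gene!r} maps to no probe")
        flag_col = f"in_{eff.tract_name}"
        if flag_col not in samples.columns:
            raise ValueError(
                f"planted pathway {eff.pathway} has no tract flag column"
            )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    n_probes, n_samples = len(probes), len(samples)
    baseline = rng.normal(7.0, 1.0, size=n_probes)
    values = baseline[:, None] + rng.normal(0.0, noise_sd, (n_probes, n_samples))
    probe_index = {p: i for i, p in enumerate(probes)}
    for eff in planted:
        in_tube = samples[f"in_{eff.tract_name}"].to_numpy(dtype=bool)
        for p in gene_probes[eff.gene]:
            values[probe_index[p], in_tube] += eff.delta
    return pd.DataFrame(
        values, index=pd.Index(probes, name="probe_id"),
        columns=samples["sample_id"].tolist(),
    )


# --------------------------------------------------------------------------
# protein-protein interaction graph
# --------------------------------------------------------------------------


def make_ppi(
    proteins: Sequence[str],
    seed_protein: str,
    design: TierDesign,
    seed: int = 0,
    genes: Sequence[str] | None = None,
    n_extra_edges: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Designed interaction graph around a seed protein.

    The seed attaches to every related protein; each designed tier-k
    protein receives exactly k unique partners inside C = {seed} U
    related (drawn from the related set, falling back to the seed only
    when k equals |C|).  Extra random edges are added among proteins
    outside C and never touch it.  Returns an undirected, deduplicated,
    self-loop-free edge table and a gene -> protein map pairing ``genes``
    (default: ``<protein>_gene``) with the roster in order.
    """
    core = [seed_protein, *design.related]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    edges: set[tuple[str, str]] = set()

    def add(u: str, v: str) -> None:
        if u != v:
            edges.add((u, v) if u < v else (v, u))

    for r in design.related:
        add(seed_protein, r)
    for tier_k, members in ((3, design.tier3), (2, design.tier2), (1, design.peripheral)):
        for prot in members:
            if tier_k > len(core):
                raise ValueError(
                    f"tier design demands {tier_k} partners for {prot!r} "
                    f"but |{{seed}} U related| = {len(core)}"
                )
            pool = list(design.related)
            if tier_k > len(pool):
                pool = core
            partners = rng.choice(len(pool), size=tier_k, replace=False)
            for idx in partners:
                add(prot, pool[idx])

    outside = [p for p in proteins if p not in core]
    for _ in range(n_extra_edges):
        if len(outside) < 2:
            break
        u, v = rng.choice(len(outside), size=2, replace=False)
        add(outside[u], outside[v])

    edge_df = pd.DataFrame(sorted(edges), columns=["protein_a", "protein_b"])
    if genes is None:
        genes = [f"{p}_gene" for p in proteins]
    gene_protein = pd.DataFrame(
        {"gene": list(genes), "protein": list(proteins)}
    )
    return edge_df, gene_protein


# --------------------------------------------------------------------------
# bundle
# --------------------------------------------------------------------------


def default_tier_design() -> TierDesign:
    """Six related proteins (mirroring the curated related-set size),
    six tier-3, six tier-2 and eight peripheral proteins."""
    return TierDesign(
        related=tuple(f"P{i:03d}" for i in range(2, 8)),
        tier3=tuple(f"P{i:03d}" for i in range(8, 14)),
        tier2=tuple(f"P{i:03d}" for i in range(14, 20)),
        peripheral=tuple(f"P{i:03d}" for i in range(20, 28)),
    )


DEFAULT_SEED_PROTEIN = "P001"


@dataclass
class SyntheticBundle:
    """Everything a pipeline run needs, generated from one master seed."""

    phantom: Phantom
    samples: pd.DataFrame
    expression: pd.DataFrame
    probe_gene: pd.DataFrame
    genes: list[str]
    disease_genes: list[str]
    gene_protein: pd.DataFrame
    ppi_edges: pd.DataFrame
    seed_protein: str
    tier_design: TierDesign
    planted: list[PlantedEffect]
    manifest: dict


def default_planted_effects() -> list[PlantedEffect]:
    return [
        PlantedEffect("G001", ("hippocampus_left", "thalamus_left"), 3.0),
        PlantedEffect("G002", ("hippocampus_left", "thalamus_left"), 3.0),
        PlantedEffect("G003", ("hippocampus_left", "thalamus_left"), 3.0),
    ]


def generate_bundle(
    seed: int = 0,
    config: PhantomConfig | None = None,
    n_samples: int = 200,
    forced_per_tract: int = 12,
    n_genes: int = 40,
    probes_per_gene: int = 2,
    noise_sd: float = 0.5,
    planted: Sequence[PlantedEffect] | None = None,
) -> SyntheticBundle:
    """Generate the full default fixture bundle from one master seed."""
    if config is None:
        config = default_phantom_config(seed=seed)
    phantom = make_phantom(config)
    samples = make_samples(
        phantom, n_samples=n_samples, seed=seed, forced_per_tract=forced_per_tract
    )
    genes = [f"G{i + 1:03d}" for i in range(n_genes)]
    probe_gene = make_probe_gene_map(genes, probes_per_gene)
    if planted is None:
        planted = default_planted_effects()
    expression = make_expression(
        samples, probe_gene, planted=planted, noise_sd=noise_sd, seed=seed
    )
    design = default_tier_design()
    n_proteins = 1 + len(design.designed)  # P001 .. P027
    proteins = [f"P{i + 1:03d}" for i in range(n_proteins + 5)]  # + extras
    mapped_genes = genes[: len(proteins)]
    ppi_edges, gene_protein = make_ppi(
        proteins,
        DEFAULT_SEED_PROTEIN,
        design,
        seed=seed,
        genes=mapped_genes,
    )
    disease_genes = genes[: n_genes * 3 // 4]  # last quarter left unmapped/undiseased
    manifest = {
        "seed": seed,
        "n_samples": n_samples,
        "forced_per_tract": forced_per_tract,
        "n_genes": n_genes,
        "probes_per_gene": probes_per_gene,
        "noise_sd": noise_sd,
        "planted": [
            {"gene": p.gene, "pathway": list(p.pathway), "delta": p.delta}
            for p in planted
        ],
        "seed_protein": DEFAULT_SEED_PROTEIN,
        "n_rois": len(config.rois),
        "n_tracts": len(config.tracts),
    }
    return SyntheticBundle(
        phantom=phantom,
        samples=samples,
        expression=expression,
        probe_gene=probe_gene,
        genes=genes,
        disease_genes=disease_genes,
        gene_protein=gene_protein,
        ppi_edges=ppi_edges,
        seed_protein=DEFAULT_SEED_PROTEIN,
        tier_design=design,
        planted=list(planted),
        manifest=manifest,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write the bundle to disk in the documented on-disk contracts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.phantom.labels.write_nifti(outdir / "labels.nii.gz")
    bundle.phantom.field.write_nifti(outdir / "orientation_field.nii.gz")
    bundle.phantom.labels.registry.write_tsv(outdir / "roi_registry.tsv")
    bundle.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    bundle.expression.to_csv(outdir / "expression.tsv", sep="\t")
    bundle.probe_gene.to_csv(outdir / "probe_gene.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": bundle.disease_genes}).to_csv(
        outdir / "disease_genes.tsv", sep="\t", index=False
    )
    bundle.gene_protein.to_csv(outdir / "gene_protein.tsv", sep="\t", index=False)
    bundle.ppi_edges.to_csv(outdir / "ppi_edges.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "protein": [bundle.seed_protein, *bundle.tier_design.related],
            "role": ["seed"] + ["related"] * len(bundle.tier_design.related),
        }
    ).to_csv(outdir / "seed_proteins.tsv", sep="\t", index=False)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(bundle.manifest, fh, sort_keys=True)
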