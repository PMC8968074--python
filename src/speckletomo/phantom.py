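"""Voxelized vascular phantoms and strand tables.

A *strand* is a continuous vessel segment between two bifurcation points
(or endpoints) of the vascular network.  The phantom builder lays out
interleaved horizontal vessel layers plus descending vessels normal to the
illuminated surface, rasterizes them onto an isotropic voxel grid, and
returns both the labeled volume and the strand table that the transport
and reconstruction stages consume.

Conventions
-----------
* Lengths in micrometers; the voxel grid is isotropic with pitch ``pitch``.
* 0-based voxel indices; the physical position of voxel (i,j,k) center is
  ``(i+0.5, j+0.5, k+0.5) * pitch``.
* z increases with depth; z = 0 is the illuminated top surface.
* Voxel label 0 is extravascular; label i > 0 belongs to strand i.
* Optical coefficients are stored in mm^-1 (the usual tabulated units) and
  converted to um^-1 only inside the transport kernel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "OpticalProperties",
    "Strand",
    "VoxelGeometry",
    "FlowMap",
    "DEFAULT_OPTICAL_LUT",
    "DEFAULT_RADIUS_FLOW_TABLE",
    "CAPILLARY_RADIUS_UM",
    "build_grid_phantom",
    "assign_flows",
    "group_capillaries",
    "merge_superstrands",
    "bifurcation_graph_from_strands",
    "save_geometry",
    "load_geometry",
    "strands_to_frame",
]

#: Radius below which a vessel is treated as part of the capillary network.
CAPILLARY_RADIUS_UM = 5.5


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption/scattering coefficients (mm^-1) and anisotropy g."""

    mu_a: float
    mu_s: float
    g: float

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s <= 0:
            raise ValueError(f"mu_s must be > 0, got {self.mu_s}")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"anisotropy g must lie in (-1, 1), got {self.g}")


#: Optical properties of the three tissue classes (mm^-1; anisotropy unitless).
DEFAULT_OPTICAL_LUT: dict[str, OpticalProperties] = {
    "capillary": OpticalProperties(mu_a=0.2, mu_s=65.0, g=0.98),
    "noncapillary": OpticalProperties(mu_a=0.2, mu_s=90.0, g=0.98),
    "extravascular": OpticalProperties(mu_a=0.02, mu_s=10.0, g=0.9),
}

#: Radius (um) -> centerline speed (mm/s) lookup, monotone in radius, spanning
#: capillary flows of ~0.3 mm/s up to ~6 mm/s in large superficial vessels.
DEFAULT_RADIUS_FLOW_TABLE: list[tuple[float, float]] = [
    (2.0, 0.3),
    (4.0, 0.4),
    (5.5, 0.6),
    (8.0, 1.2),
    (12.0, 2.2),
    (18.0, 4.0),
    (25.0, 6.0),
]


@dataclass
class Strand:
    """One vessel trace: ordered centerline polyline with a single radius.

    ``group_id`` identifies the flow unknown the strand belongs to; it
    equals the strand's own id unless capillary grouping merged it with
    neighbours.  ``orientation`` ("horizontal"/"descending") and
    ``depth_um`` are bookkeeping labels used in error stratification.
    """

    id: int
    centerline: np.ndarray  # (M, 3) um
    radius: float  # um
    tissue_class: str = "noncapillary"
    group_id: int = -1
    orientation: str = "horizontal"
    depth_um: float = 0.0
    directions: np.ndarray = field(default=None, repr=False)  # (M, 3) unit tangents

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=np.float64)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3:
            raise ValueError("centerline must be an (M, 3) array")
        if self.radius <= 0:
            raise ValueError(f"strand {self.id}: radius must be > 0")
        if self.group_id < 0:
            self.group_id = self.id
        if self.directions is None:
            self.directions = _polyline_tangents(self.centerline)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1).sum())

    @property
    def centroid(self) -> np.ndarray:
        return self.centerline.mean(axis=0)

    @property
    def is_capillary(self) -> bool:
        return self.tissue_class == "capillary"


def _polyline_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangent at each polyline vertex (forward/backward at the ends)."""
    if len(points) == 1:
        raise ValueError("centerline needs at least 2 points")
    seg = np.diff(points, axis=0)
    seg = seg / np.maximum(np.linalg.norm(seg, axis=1, keepdims=True), 1e-300)
    tang = np.empty_like(points)
    tang[0] = seg[0]
    tang[-1] = seg[-1]
    if len(points) > 2:
        mid = seg[:-1] + seg[1:]
        tang[1:-1] = mid / np.maximum(np.linalg.norm(mid, axis=1, keepdims=True), 1e-300)
    return tang


@dataclass
class VoxelGeometry:
    """Labeled voxel grid plus the per-voxel centerline direction field.

    ``label[i,j,k]`` is the strand id occupying the voxel (0 extravascular).
    ``voxel_dir`` holds the unit tangent of the owning strand at the nearest
    centerline point, zero outside vessels; the transport kernel needs it to
    project photon momentum transfer onto the local flow direction.
    """

    shape: tuple[int, int, int]
    pitch: float  # um
    label: np.ndarray  # (nx, ny, nz) int32
    voxel_dir: np.ndarray  # (nx, ny, nz, 3) float32
    optical_lut: dict[str, OpticalProperties] = field(
        default_factory=lambda: dict(DEFAULT_OPTICAL_LUT)
    )

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")
        if tuple(self.label.shape) != tuple(self.shape):
            raise ValueError("label array does not match declared shape")

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple(s * self.pitch for s in self.shape)

    def class_grid(self, strands: list[Strand]) -> np.ndarray:
        """uint8 per-voxel tissue class: 0 extravascular, 1 capillary, 2 noncapillary."""
        lut = np.zeros(int(self.label.max()) + 1, dtype=np.uint8)
        for s in strands:
            lut[s.id] = 1 if s.is_capillary else 2
        return lut[self.label]

    def group_index_grid(self, strands: list[Strand], group_ids: np.ndarray) -> np.ndarray:
        """int32 per-voxel index into ``group_ids`` (-1 extravascular)."""
        pos = {int(g): i for i, g in enumerate(group_ids)}
        lut = np.full(int(self.label.max()) + 1, -1, dtype=np.int32)
        for s in strands:
            lut[s.id] = pos[int(s.group_id)]
        return lut[self.label]


@dataclass
class FlowMap:
    """Per-group scalar centerline speeds in mm/s, the unknown of the inversion."""

    group_ids: np.ndarray  # (G,) int
    v: np.ndarray  # (G,) mm/s

    def __post_init__(self) -> None:
        self.group_ids = np.asarray(self.group_ids, dtype=np.int64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.group_ids.shape != self.v.shape:
            raise ValueError("group_ids and v must align")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("flows must be finite")
        if np.any(self.v < 0):
            raise ValueError("flows must be non-negative")

    def __getitem__(self, group_id: int) -> float:
        idx = np.nonzero(self.group_ids == group_id)[0]
        if len(idx) == 0:
            raise KeyError(f"no flow for group {group_id}")
        return float(self.v[idx[0]])

    def vector(self, group_order: np.ndarray) -> np.ndarray:
        """Speeds re-indexed to ``group_order``; raises on a missing group."""
        pos = {int(g): i for i, g in enumerate(self.group_ids)}
        try:
            return self.v[[pos[int(g)] for g in group_order]]
        except KeyError as exc:
            raise KeyError(f"no flow for group {exc.args[0]}") from None


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------


def build_grid_phantom(
    extent: tuple[float, float, float],
    pitch: float,
    layer_depths: list[float],
    descending_spacing: tuple[float, float],
    radii: list[float],
    *,
    vessels_per_layer: int = 3,
    descending_radius: float | None = None,
    descending_depth: float | None = None,
    capillary_radius_um: float = CAPILLARY_RADIUS_UM,
    optical_lut: dict[str, OpticalProperties] | None = None,
) -> tuple[VoxelGeometry, list[Strand]]:
    """Build the grid phantom: interleaved horizontal layers + descending vessels.

    Horizontal vessels in layer ``i`` run along x for even ``i`` and along y
    for odd ``i`` (interleaved), at depth ``layer_depths[i]``, with radius
    ``radii[i]``.  Descending vessels are normal to the surface on a lattice
    spaced by ``descending_spacing``; they start as T-junctions at the first
    layer depth (bifurcating immediately below the first layer) and extend to
    ``descending_depth``.

    Returns the rasterized :class:`VoxelGeometry` and the strand table.
    """
    extent = tuple(float(e) for e in extent)
    for e in extent:
        if abs(e / pitch - round(e / pitch)) > 1e-9:
            raise ValueError(f"extent {e} um is not divisible by pitch {pitch} um")
    shape = tuple(int(round(e / pitch)) for e in extent)
    if layer_depths and max(layer_depths) > extent[2]:
        raise ValueError("layer depths exceed the z extent")
    if len(radii) < len(layer_depths):
        raise ValueError("need one radius per horizontal layer")

    strands: list[Strand] = []
    next_id = 1
    for i, depth in enumerate(layer_depths):
        along_x = i % 2 == 0
        lateral_extent = extent[1] if along_x else extent[0]
        run = extent[0] if along_x else extent[1]
        for j in range(vessels_per_layer):
            off = (j + 0.5) * lateral_extent / vessels_per_layer
            if along_x:
                p0, p1 = (0.0, off, depth), (run, off, depth)
            else:
                p0, p1 = (off, 0.0, depth), (off, run, depth)
            r = radii[i]
            strands.append(
                Strand(
                    id=next_id,
                    centerline=np.array([p0, p1]),
                    radius=r,
                    tissue_class="capillary" if r < capillary_radius_um else "noncapillary",
                    orientation="horizontal",
                    depth_um=depth,
                )
            )
            next_id += 1

    if layer_depths:
        dx, dy = descending_spacing
        xs = np.arange(dx / 2, extent[0], dx) if dx > 0 else np.array([extent[0] / 2])
        ys = np.arange(dy / 2, extent[1], dy) if dy > 0 else np.array([extent[1] / 2])
        z0 = layer_depths[0]
        z1 = descending_depth if descending_depth is not None else extent[2] - 10 * pitch
        z1 = min(z1, extent[2] - pitch)
        r_desc = descending_radius if descending_radius is not None else radii[-1]
        for x in xs:
            for y in ys:
                strands.append(
                    Strand(
                        id=next_id,
                        centerline=np.array([(x, y, z0), (x, y, z1)]),
                        radius=r_desc,
                        tissue_class="capillary" if r_desc < capillary_radius_um else "noncapillary",
                        orientation="descending",
                        depth_um=0.5 * (z0 + z1),
                    )
                )
                next_id += 1

    _check_parallel_overlaps(strands)
    geometry = rasterize_strands(shape, pitch, strands, optical_lut=optical_lut)
    return geometry, strands


def _check_parallel_overlaps(strands: list[Strand]) -> None:
    """Reject truly overlapping (near-parallel, interpenetrating) vessel pairs.

    Junctions between non-parallel vessels are legitimate; two parallel
    vessels whose centerlines run closer than the sum of their radii are a
    specification error.
    """
    for a_i in range(len(strands)):
        for b_i in range(a_i + 1, len(strands)):
            a, b = strands[a_i], strands[b_i]
            da, db = a.directions[0], b.directions[0]
            if abs(float(np.dot(da, db))) < 0.999:
                continue
            d = _segment_segment_distance(
                a.centerline[0], a.centerline[-1], b.centerline[0], b.centerline[-1]
            )
            if d < a.radius + b.radius:
                raise ValueError(
                    f"strands {a.id} and {b.id} overlap: parallel centerlines "
                    f"{d:.1f} um apart with radii {a.radius} + {b.radius} um"
                )


def _segment_segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 3D segments (coarse sampled; phantom QA only)."""
    t = np.linspace(0.0, 1.0, 33)
    pa = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    qa = q0[None, :] + t[:, None] * (q1 - q0)[None, :]
    d = np.linalg.norm(pa[:, None, :] - qa[None, :, :], axis=2)
    return float(d.min())


def rasterize_strands(
    shape: tuple[int, int, int],
    pitch: float,
    strands: list[Strand],
    optical_lut: dict[str, OpticalProperties] | None = None,
) -> VoxelGeometry:
    """Rasterize strands onto the voxel grid.

    A voxel is vascular iff its center lies within ``radius`` of the strand
    centerline; where vessels overlap the nearest centerline wins.
    """
    nx, ny, nz = shape
    label = np.zeros(shape, dtype=np.int32)
    vdir = np.zeros(shape + (3,), dtype=np.float32)
    best = np.full(shape, np.inf, dtype=np.float32)

    centers = [(np.arange(n) + 0.5) * pitch for n in shape]

    for s in strands:
        pts = s.centerline
        for k in range(len(pts) - 1):
            a, b = pts[k], pts[k + 1]
            d = b - a
            seg_len = np.linalg.norm(d)
            if seg_len == 0:
                continue
            dn = d / seg_len
            lo = np.minimum(a, b) - s.radius - pitch
            hi = np.maximum(a, b) + s.radius + pitch
            i0 = [max(0, int(np.floor(lo[ax] / pitch))) for ax in range(3)]
            i1 = [min(shape[ax], int(np.ceil(hi[ax] / pitch)) + 1) for ax in range(3)]
            if any(i0[ax] >= i1[ax] for ax in range(3)):
                continue
            X, Y, Z = np.meshgrid(
                centers[0][i0[0] : i1[0]],
                centers[1][i0[1] : i1[1]],
                centers[2][i0[2] : i1[2]],
                indexing="ij",
            )
            P = np.stack([X, Y, Z], axis=-1) - a
            t = np.clip(P @ d / seg_len**2, 0.0, 1.0)
            closest = t[..., None] * d
            dist = np.linalg.norm(P - closest, axis=-1)
            sub = (
                slice(i0[0], i1[0]),
                slice(i0[1], i1[1]),
                slice(i0[2], i1[2]),
            )
            win = (dist <= s.radius) & (dist < best[sub])
            if not win.any():
                continue
            best[sub] = np.where(win, dist, best[sub])
            lbl = label[sub]
            lbl[win] = s.id
            label[sub] = lbl
            dsub = vdir[sub]
            dsub[win] = dn.astype(np.float32)
            vdir[sub] = dsub

    return VoxelGeometry(
        shape=tuple(shape),
        pitch=float(pitch),
        label=label,
        voxel_dir=vdir,
        optical_lut=dict(optical_lut or DEFAULT_OPTICAL_LUT),
    )


# ---------------------------------------------------------------------------
# Flow assignment and grouping
# ---------------------------------------------------------------------------


def assign_flows(
    strands: list[Strand],
    mode: str = "uniform_random",
    *,
    lo: float = 0.3,
    hi: float = 5.0,
    table: list[tuple[float, float]] | None = None,
    seed: int | None = None,
) -> FlowMap:
    """Assign one ground-truth centerline speed (mm/s) per flow group.

    ``mode="uniform_random"`` draws uniformly in ``[lo, hi]``;
    ``mode="radius_lookup"`` interpolates a monotone radius->speed table,
    clamping (with a warning) radii outside the tabulated range.
    """
    group_ids = np.unique([s.group_id for s in strands])
    if mode == "uniform_random":
        rng = np.random.default_rng(seed)
        v = rng.uniform(lo, hi, size=len(group_ids))
    elif mode == "radius_lookup":
        tab = table if table is not None else DEFAULT_RADIUS_FLOW_TABLE
        r_tab = np.array([r for r, _ in tab], dtype=float)
        v_tab = np.array([vv for _, vv in tab], dtype=float)
        if np.any(np.diff(r_tab) <= 0):
            raise ValueError("lookup table radii must be strictly increasing")
        if np.any(np.diff(v_tab) < 0):
            raise ValueError("lookup table speeds must be monotone nondecreasing")
        radii = np.array(
            [np.mean([s.radius for s in strands if s.group_id == g]) for g in group_ids]
        )
        if np.any(radii < r_tab[0]) or np.any(radii > r_tab[-1]):
            warnings.warn("some radii fall outside the lookup table; clamping to nearest bin")
        v = np.interp(radii, r_tab, v_tab)
    else:
        raise ValueError(f"unknown flow assignment mode {mode!r}")
    return FlowMap(group_ids=group_ids, v=v)


def group_capillaries(strands: list[Strand], cube_size: float = 250.0) -> list[Strand]:
    """Give capillary strands sharing a cubic region one flow unknown.

    Capillaries whose centerline centroid falls in the same axis-aligned
    cube of side ``cube_size`` um share a ``group_id`` (the smallest strand
    id in the cube).  Noncapillaries keep their own id.  Idempotent.
    """
    if cube_size <= 0:
        raise ValueError("cube_size must be > 0")
    out = [replace(s) for s in strands]
    cubes: dict[tuple[int, int, int], list[Strand]] = {}
    for s in out:
        if not s.is_capillary:
            s.group_id = s.id
            continue
        key = tuple(int(np.floor(c / cube_size)) for c in s.centroid)
        cubes.setdefault(key, []).append(s)
    for members in cubes.values():
        gid = min(m.id for m in members)
        for m in members:
            m.group_id = gid
    return out


# ---------------------------------------------------------------------------
# Superstrand merging
# ---------------------------------------------------------------------------


def bifurcation_graph_from_strands(
    strands: list[Strand], tol: float = 1e-6
) -> dict[tuple[float, float, float], list[int]]:
    """Endpoint-incidence graph: node position -> incident strand ids."""
    nodes: dict[tuple[float, float, float], list[int]] = {}
    for s in strands:
        for p in (s.centerline[0], s.centerline[-1]):
            key = tuple(np.round(p / max(tol, 1e-12)).astype(np.int64) * tol)
            key = tuple(float(x) for x in key)
            nodes.setdefault(key, []).append(s.id)
    return nodes


def merge_superstrands(
    strands: list[Strand],
    bifurcation_graph: dict[tuple[float, float, float], list[int]] | None = None,
) -> list[Strand]:
    """Concatenate the two largest-radius strands at every bifurcation.

    Yields longer, more continuous "superstrand" traces that still
    partition the network into 1D traces between bifurcations/endpoints.
    Radius ties break toward the lower strand id.  The merged trace keeps
    the smallest participating id and a length-weighted mean radius.
    """
    if bifurcation_graph is None:
        bifurcation_graph = bifurcation_graph_from_strands(strands)
    by_id = {s.id: s for s in strands}

    # Union-find over (strand, end) couplings chosen at each bifurcation.
    parent = {s.id: s.id for s in strands}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    links: list[tuple[int, int]] = []
    for node, incident in bifurcation_graph.items():
        uniq = sorted(set(incident))
        if len(uniq) < 3:
            continue
        ranked = sorted(uniq, key=lambda i: (-by_id[i].radius, i))
        links.append((ranked[0], ranked[1]))

    for a, b in links:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    clusters: dict[int, list[int]] = {}
    for s in strands:
        clusters.setdefault(find(s.id), []).append(s.id)

    merged: list[Strand] = []
    for root, ids in sorted(clusters.items()):
        if len(ids) == 1:
            merged.append(replace(by_id[ids[0]]))
            continue
        chain = _order_chain([by_id[i] for i in ids])
        lengths = np.array([by_id[i].length for i in ids])
        radius = float(np.average([by_id[i].radius for i in ids], weights=lengths))
        tissue = by_id[root].tissue_class
        merged.append(
            Strand(
                id=root,
                centerline=chain,
                radius=radius,
                tissue_class=tissue,
                group_id=root,
                orientation=by_id[root].orientation,
                depth_um=float(np.mean([by_id[i].depth_um for i in ids])),
            )
        )
    return merged


def _order_chain(members: list[Strand]) -> np.ndarray:
    """Concatenate member polylines into one trace, reorienting as needed."""
    def key(p):
        return tuple(np.round(p, 6))

    ends: dict[tuple, list[int]] = {}
    for i, s in enumerate(members):
        for p in (s.centerline[0], s.centerline[-1]):
            ends.setdefault(key(p), []).append(i)
    # chain endpoints appear once
    free = [k for k, v in ends.items() if len(v) == 1]
    if not free:  # cycle; start anywhere
        start_pt = key(members[0].centerline[0])
    else:
        start_pt = sorted(free)[0]
    used = [False] * len(members)
    pts: list[np.ndarray] = []
    cur = start_pt
    for _ in range(len(members)):
        nxt = None
        for i in ends.get(cur, []):
            if not used[i]:
                nxt = i
                break
        if nxt is None:
            break
        used[nxt] = True
        line = members[nxt].centerline
        if key(line[0]) != cur:
            line = line[::-1]
        if pts:
            line = line[1:]
        pts.append(line)
        cur = key(pts[-1][-1]) if len(pts[-1]) else cur
    return np.vstack(pts)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def strands_to_frame(strands: list[Strand]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [s.id for s in strands],
            "group_id": [s.group_id for s in strands],
            "radius_um": [s.radius for s in strands],
            "tissue_class": [s.tissue_class for s in strands],
            "orientation": [s.orientation for s in strands],
            "depth_um": [s.depth_um for s in strands],
            "n_points": [len(s.centerline) for s in strands],
        }
    )


def save_geometry(path_prefix: str, geometry: VoxelGeometry, strands: list[Strand]) -> None:
    """Write labels as a multipage TIFF (z pages), plus JSON/CSV sidecars."""
    import tifffile

    tifffile.imwrite(
        f"{path_prefix}_labels.tif",
        np.moveaxis(geometry.label, 2, 0).astype(np.int32),
    )
    meta = {
        "pitch_um": geometry.pitch,
        "shape": list(geometry.shape),
        "optical_lut": {
            k: {"mu_a": v.mu_a, "mu_s": v.mu_s, "g": v.g}
            for k, v in geometry.optical_lut.items()
        },
    }
    with open(f"{path_prefix}_geometry.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    strands_to_frame(strands).to_csv(f"{path_prefix}_strands.csv", index=False)
    poly = {str(s.id): s.centerline.tolist() for s in strands}
    with open(f"{path_prefix}_polylines.json", "w") as fh:
        json.dump(poly, fh)


def load_geometry(path_prefix: str) -> tuple[VoxelGeometry, list[Strand]]:
    import tifffile

    with open(f"{path_prefix}_geometry.json") as fh:
        meta = json.load(fh)
    label = np.moveaxis(tifffile.imread(f"{path_prefix}_labels.tif"), 0, 2).astype(np.int32)
    lut = {
        k: OpticalProperties(**v) for k, v in meta["optical_lut"].items()
    }
    table = pd.read_csv(f"{path_prefix}_strands.csv")
    with open(f"{path_prefix}_polylines.json") as fh:
        poly = json.load(fh)
    strands = [
        Strand(
            id=int(row.id),
            centerline=np.array(poly[str(int(row.id))]),
            radius=float(row.radius_um),
            tissue_class=str(row.tissue_class),
            group_id=int(row.group_id),
            orientation=str(row.orientation),
            depth_um=float(row.depth_um),
        )
        for row in table.itertuples()
    ]
    geometry = rasterize_strands(tuple(label.shape), float(meta["pitch_um"]), strands, lut)
    # keep the stored labels authoritative
    geometry = replace(geometry, label=label)
    return geometry, strands
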