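"""Photon transport through the voxelized geometry.

``simulate`` launches a collimated pencil beam at the top surface and
tracks photons through the labeled voxel grid with exact ray-voxel
stepping, Henyey-Greenstein scattering, continuous path-length absorption
weighting and Russian-roulette termination.  For every photon reflected
back through the top surface it records the exit position, the absorption
weight P_n = exp(-sum mu_a * l), and the per-flow-group momentum-transfer
coefficients q_ni = sum over dynamic scattering events in group i of
(k_out - k_in) . d_hat, where d_hat is the local centerline direction.
Scattering outside vessels leaves q untouched (static scattering).

``bin_detectors`` assigns detected photons to camera pixels, applies the
circular aperture and the per-source exclusion disk, and normalizes the
weights within each pixel so that g1(0) = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np
import scipy.sparse as sp

from . import _kernels
from .phantom import FlowMap, Strand, VoxelGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "SourceSpec",
    "DetectorGrid",
    "PhotonRecord",
    "PhotonRecords",
    "DetectorPhotons",
    "BinnedSource",
    "simulate",
    "bin_detectors",
    "save_trajectories",
    "load_trajectories",
]

#: Russian-roulette weight threshold and survival probability.
RR_THRESHOLD = 1e-4
RR_SURVIVE = 0.1
#: Hard cap on scattering events per photon.
MAX_EVENTS = 100_000

_CLASS_INDEX = {"extravascular": 0, "capillary": 1, "noncapillary": 2}


@dataclass(frozen=True)
class SourceSpec:
    """Collimated normal-incidence beam on the top surface."""

    position: tuple[float, float]  # (x, y) um
    beam_diameter: float = 40.0  # um
    source_id: int = 0

    def __post_init__(self) -> None:
        if self.beam_diameter <= 0:
            raise ValueError("beam diameter must be > 0")


@dataclass(frozen=True)
class DetectorGrid:
    """Square camera pixel grid with circular aperture and source exclusion."""

    n: int  # pixels per side
    pixel_size: float  # um
    center: tuple[float, float]  # um
    exclusion_radius: float = 200.0  # um around the source
    aperture_radius: float | None = None  # circular detection region; None = half FOV

    def __post_init__(self) -> None:
        if self.n <= 0 or self.pixel_size <= 0:
            raise ValueError("detector grid must have n > 0 and pixel_size > 0")
        if self.exclusion_radius < 0:
            raise ValueError("exclusion_radius must be >= 0")

    @property
    def origin(self) -> tuple[float, float]:
        half = self.n * self.pixel_size / 2.0
        return (self.center[0] - half, self.center[1] - half)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        c = (np.arange(self.n) + 0.5) * self.pixel_size
        return x0 + c, y0 + c

    def valid_mask(self, source: SourceSpec) -> np.ndarray:
        """(n, n) bool mask: inside the aperture, outside the exclusion disk."""
        xc, yc = self.pixel_centers()
        X, Y = np.meshgrid(xc, yc, indexing="ij")
        ap = self.aperture_radius
        if ap is None:
            ap = self.n * self.pixel_size / 2.0
        inside = (X - self.center[0]) ** 2 + (Y - self.center[1]) ** 2 <= ap**2
        sx, sy = source.position
        excl = (X - sx) ** 2 + (Y - sy) ** 2 < self.exclusion_radius**2
        return inside & ~excl


@dataclass(frozen=True)
class PhotonRecord:
    """One detected photon (convenience view; bulk storage is columnar)."""

    source_id: int
    detector_id: int
    weight: float
    q: dict[int, float]  # group_id -> momentum-transfer coefficient


class PhotonRecords:
    """Columnar store of the detected photons of one source.

    ``Q`` is the sparse (G, M) momentum-transfer coefficient matrix
    (rows = flow groups in ``group_ids`` order, columns = photons);
    ``weights`` are the raw absorption weights before per-detector
    normalization.
    """

    def __init__(
        self,
        source: SourceSpec,
        n_launched: int,
        seed: int,
        exit_xy: np.ndarray,
        weights: np.ndarray,
        Q: sp.csc_matrix,
        group_ids: np.ndarray,
    ) -> None:
        self.source = source
        self.n_launched = int(n_launched)
        self.seed = int(seed)
        self.exit_xy = exit_xy
        self.weights = weights
        self.Q = Q.tocsc()
        self.group_ids = np.asarray(group_ids, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def n_dynamic(self) -> int:
        return int(np.count_nonzero(np.diff(self.Q.indptr)))

    def iter_records(self, detector_ids: np.ndarray | None = None):
        """Yield :class:`PhotonRecord` views (small problems / tests only)."""
        Q = self.Q
        for j in range(len(self)):
            lo, hi = Q.indptr[j], Q.indptr[j + 1]
            q = {int(self.group_ids[Q.indices[k]]): float(Q.data[k]) for k in range(lo, hi)}
            det = -1 if detector_ids is None else int(detector_ids[j])
            yield PhotonRecord(self.source.source_id, det, float(self.weights[j]), q)


def simulate(
    geometry: VoxelGeometry,
    strands: list[Strand],
    source: SourceSpec,
    n_photons: int,
    seed: int,
    *,
    chunk_size: int = 200_000,
) -> PhotonRecords:
    """Run the transport Monte Carlo for one source.

    Photons exiting any face other than the top, or killed by roulette or
    the event cap, are discarded.  Bit-reproducible for fixed seed and
    ``n_photons`` irrespective of chunking.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    lx, ly, _ = geometry.extent
    sx, sy = source.position
    r_beam = source.beam_diameter / 2.0
    if not (r_beam <= sx <= lx - r_beam and r_beam <= sy <= ly - r_beam):
        raise ValueError("beam does not fit inside the top surface")

    group_ids = np.unique([s.group_id for s in strands]) if strands else np.empty(0, np.int64)
    cls_grid = geometry.class_grid(strands)
    gidx = geometry.group_index_grid(strands, group_ids)
    lut = geometry.optical_lut
    order = ["extravascular", "capillary", "noncapillary"]
    # mm^-1 -> um^-1
    mu_a = np.array([lut[k].mu_a / 1000.0 for k in order])
    mu_s = np.array([lut[k].mu_s / 1000.0 for k in order])
    g_hg = np.array([lut[k].g for k in order])

    # coarse occupancy blocks let the kernel skip vessel-free space
    block = 8
    nbx, nby, nbz = (int(np.ceil(s / block)) for s in geometry.shape)
    occ = np.zeros((nbx, nby, nbz), dtype=np.uint8)
    vx, vy, vz = np.nonzero(geometry.label)
    occ[vx // block, vy // block, vz // block] = 1
    if occ.any():
        from scipy.ndimage import distance_transform_cdt

        occ_dist = distance_transform_cdt(1 - occ, metric="chessboard").astype(np.int16)
    else:
        occ_dist = np.full(occ.shape, np.int16(max(occ.shape) + 1))

    G = len(group_ids)
    xs, ys, ws, qs = [], [], [], []
    launched = 0
    while launched < n_photons:
        n_chunk = min(chunk_size, n_photons - launched)
        out_det = np.zeros(n_chunk, dtype=np.uint8)
        out_x = np.zeros(n_chunk)
        out_y = np.zeros(n_chunk)
        out_w = np.zeros(n_chunk)
        out_q = np.zeros((n_chunk, max(G, 1)))
        out_ns = np.zeros(n_chunk, dtype=np.int32)
        _kernels.transport_chunk(
            cls_grid,
            gidx,
            geometry.voxel_dir,
            occ,
            occ_dist,
            block,
            mu_a,
            mu_s,
            g_hg,
            geometry.pitch,
            sx,
            sy,
            r_beam,
            n_chunk,
            launched,
            seed,
            RR_THRESHOLD,
            RR_SURVIVE,
            MAX_EVENTS,
            out_det,
            out_x,
            out_y,
            out_w,
            out_q,
            out_ns,
        )
        det = out_det.astype(bool)
        xs.append(out_x[det])
        ys.append(out_y[det])
        ws.append(out_w[det])
        qs.append(sp.csr_matrix(out_q[det][:, :G] if G else np.zeros((det.sum(), 0))))
        launched += n_chunk

    exit_xy = np.stack([np.concatenate(xs), np.concatenate(ys)], axis=1)
    weights = np.concatenate(ws)
    Q = sp.vstack(qs).T.tocsc() if G else sp.csc_matrix((0, len(weights)))
    logger.info(
        "source %d: launched %d, detected %d (%.1f%%), dynamic %d",
        source.source_id,
        n_photons,
        len(weights),
        100.0 * len(weights) / n_photons,
        int(np.count_nonzero(np.diff(Q.indptr))) if G else 0,
    )
    return PhotonRecords(source, n_photons, seed, exit_xy, weights, Q, group_ids)


@dataclass
class DetectorPhotons:
    """Photons of one detector with per-detector normalized weights."""

    weights: np.ndarray  # (M,), sums to 1
    Q: sp.csc_matrix  # (G, M)
    group_ids: np.ndarray
    detector_id: int = -1
    source_id: int = 0

    @property
    def n_photons(self) -> int:
        return len(self.weights)

    def dynamic_mask(self) -> np.ndarray:
        return np.diff(self.Q.indptr) > 0

    def split_static(self):
        """(P_dyn, Qd_dense, s0, sum_ps2) for the pair kernels."""
        dyn = self.dynamic_mask()
        w_static = self.weights[~dyn]
        P_dyn = np.ascontiguousarray(self.weights[dyn], dtype=np.float64)
        Qd = np.ascontiguousarray(self.Q[:, np.nonzero(dyn)[0]].toarray(), dtype=np.float64)
        return P_dyn, Qd, float(w_static.sum()), float((w_static**2).sum())


class BinnedSource:
    """Detected photons of one source, sorted by camera pixel.

    ``offsets[p]:offsets[p+1]`` slices the photon arrays for flat pixel
    index ``p`` (row-major over the (n, n) grid).  ``mask`` marks usable
    pixels (aperture / exclusion); pixels with zero photons are flagged
    empty and skipped downstream.
    """

    def __init__(
        self,
        records: PhotonRecords,
        grid: DetectorGrid,
        offsets: np.ndarray,
        weights: np.ndarray,
        Q: sp.csc_matrix,
        mask: np.ndarray,
        n_dropped: int,
    ) -> None:
        self.source = records.source
        self.grid = grid
        self.group_ids = records.group_ids
        self.n_launched = records.n_launched
        self.seed = records.seed
        self.offsets = offsets
        self.weights = weights  # per-pixel normalized
        self.Q = Q
        self.QT = Q.T.tocsr()  # (M, G) for fast Y = QT @ v
        self.mask = mask
        self.n_dropped = n_dropped
        self._prepared: list | None = None

    @property
    def n_pixels(self) -> int:
        return self.grid.n * self.grid.n

    def counts(self) -> np.ndarray:
        return np.diff(self.offsets)

    def valid_pixels(self) -> np.ndarray:
        """Flat indices of usable, non-empty pixels."""
        usable = self.mask.ravel() & (self.counts() > 0)
        return np.nonzero(usable)[0]

    def detector(self, pixel: int) -> DetectorPhotons:
        lo, hi = self.offsets[pixel], self.offsets[pixel + 1]
        if hi == lo:
            raise ValueError(f"detector {pixel} is empty (no detected photons)")
        return DetectorPhotons(
            weights=self.weights[lo:hi],
            Q=self.Q[:, lo:hi],
            group_ids=self.group_ids,
            detector_id=pixel,
            source_id=self.source.source_id,
        )

    def momentum_transfers(self, flows: FlowMap) -> np.ndarray:
        """Per-photon Y (um/s) for all detected photons at the given flows."""
        v_um = flows.vector(self.group_ids) * 1000.0
        return self.QT.dot(v_um)

    def prepared_detectors(self) -> list:
        """Per valid pixel: (pixel, dyn_idx, P_dyn, Qd, s0, sum_ps2), cached."""
        if self._prepared is None:
            nnz = np.diff(self.Q.indptr) > 0
            out = []
            for p in self.valid_pixels():
                lo, hi = self.offsets[p], self.offsets[p + 1]
                dyn = nnz[lo:hi]
                dyn_idx = lo + np.nonzero(dyn)[0]
                w = self.weights[lo:hi]
                P_dyn = np.ascontiguousarray(w[dyn], dtype=np.float64)
                Qd = np.ascontiguousarray(self.Q[:, dyn_idx].toarray(), dtype=np.float64)
                ws = w[~dyn]
                out.append((int(p), dyn_idx, P_dyn, Qd, float(ws.sum()), float((ws**2).sum())))
            self._prepared = out
            dyn_cat = (
                np.concatenate([rec[1] for rec in out])
                if out
                else np.empty(0, dtype=np.int64)
            )
            Qdyn = self.Q[:, dyn_cat].T.tocsr()
            Qdyn.sort_indices()
            spans = np.zeros(len(out) + 1, dtype=np.int64)
            spans[1:] = np.cumsum([len(rec[1]) for rec in out])
            self._Qdyn = Qdyn
            self._dyn_spans = spans
        return self._prepared

    def dyn_momentum(self, v_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Momentum transfers of the dynamic photons of all valid pixels.

        Returns (Y, spans): ``Y[spans[i]:spans[i+1]]`` are the per-photon
        Y values (um/s) for the i-th record of :meth:`prepared_detectors`.
        The single canonical sparse product keeps model contrasts
        bit-identical between image generation and reconstruction.
        """
        self.prepared_detectors()
        return self._Qdyn.dot(v_um), self._dyn_spans

    def dynamic_photon_counts(self) -> np.ndarray:
        """Per-group count of dynamically scattered photons in usable pixels."""
        counts = np.zeros(len(self.group_ids), dtype=np.int64)
        for _, _, _, Qd, _, _ in self.prepared_detectors():
            counts += (Qd != 0).sum(axis=1)
        return counts


def bin_detectors(records: PhotonRecords, grid: DetectorGrid) -> BinnedSource:
    """Assign detected photons to pixels and normalize weights per pixel.

    Photons exiting outside the grid are dropped (counted in the log);
    pixel assignment uses half-open intervals [edge, edge + pixel_size).
    """
    x0, y0 = grid.origin
    px = np.floor((records.exit_xy[:, 0] - x0) / grid.pixel_size).astype(np.int64)
    py = np.floor((records.exit_xy[:, 1] - y0) / grid.pixel_size).astype(np.int64)
    inside = (px >= 0) & (px < grid.n) & (py >= 0) & (py < grid.n)
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.info("binning: dropped %d photons outside the detector grid", n_dropped)
    flat = px[inside] * grid.n + py[inside]
    order = np.argsort(flat, kind="stable")
    flat_sorted = flat[order]
    keep = np.nonzero(inside)[0][order]

    offsets = np.zeros(grid.n * grid.n + 1, dtype=np.int64)
    np.add.at(offsets[1:], flat_sorted, 1)
    offsets = np.cumsum(offsets)

    weights = records.weights[keep].astype(np.float64)
    # per-detector normalization so that each detector's weights sum to 1
    for p in range(grid.n * grid.n):
        lo, hi = offsets[p], offsets[p + 1]
        if hi > lo:
            weights[lo:hi] /= weights[lo:hi].sum()
    Q = records.Q[:, keep].tocsc()
    mask = grid.valid_mask(records.source)
    if not (mask.ravel() & (np.diff(offsets) > 0)).any():
        logger.warning(
            "source %d: no usable detectors after masking", records.source.source_id
        )
    return BinnedSource(records, grid, offsets, weights, Q, mask, n_dropped)


# ---------------------------------------------------------------------------
# HDF5 trajectory store
# ---------------------------------------------------------------------------


def save_trajectories(path: str, binned: BinnedSource) -> None:
    """One HDF5 file per source: binned weights and CSR-style sparse q."""
    with h5py.File(path, "w") as fh:
        fh.attrs["source_id"] = binned.source.source_id
        fh.attrs["source_position"] = binned.source.position
        fh.attrs["beam_diameter"] = binned.source.beam_diameter
        fh.attrs["n_launched"] = binned.n_launched
        fh.attrs["seed"] = binned.seed
        fh.attrs["grid_n"] = binned.grid.n
        fh.attrs["grid_pixel_size"] = binned.grid.pixel_size
        fh.attrs["grid_center"] = binned.grid.center
        fh.attrs["exclusion_radius"] = binned.grid.exclusion_radius
        ap = binned.grid.aperture_radius
        fh.attrs["aperture_radius"] = -1.0 if ap is None else ap
        fh.attrs["n_dropped"] = binned.n_dropped
        fh.create_dataset("group_ids", data=binned.group_ids)
        fh.create_dataset("offsets", data=binned.offsets)
        fh.create_dataset("weights", data=binned.weights)
        fh.create_dataset("mask", data=binned.mask)
        Q = binned.Q.tocsc()
        fh.create_dataset("q_data", data=Q.data)
        fh.create_dataset("q_indices", data=Q.indices)
        fh.create_dataset("q_indptr", data=Q.indptr)


def load_trajectories(path: str) -> BinnedSource:
    with h5py.File(path, "r") as fh:
        source = SourceSpec(
            position=tuple(fh.attrs["source_position"]),
            beam_diameter=float(fh.attrs["beam_diameter"]),
            source_id=int(fh.attrs["source_id"]),
        )
        ap = float(fh.attrs["aperture_radius"])
        grid = DetectorGrid(
            n=int(fh.attrs["grid_n"]),
            pixel_size=float(fh.attrs["grid_pixel_size"]),
            center=tuple(fh.attrs["grid_center"]),
            exclusion_radius=float(fh.attrs["exclusion_radius"]),
            aperture_radius=None if ap < 0 else ap,
        )
        group_ids = fh["group_ids"][:]
        offsets = fh["offsets"][:]
        weights = fh["weights"][:]
        mask = fh["mask"][:].astype(bool)
        Q = sp.csc_matrix(
            (fh["q_data"][:], fh["q_indices"][:], fh["q_indptr"][:]),
            shape=(len(group_ids), len(weights)),
        )
        records = PhotonRecords(
            source,
            int(fh.attrs["n_launched"]),
            int(fh.attrs["seed"]),
            np.zeros((len(weights), 2)),
            weights,
            Q,
            group_ids,
        )
        return BinnedSource(
            records, grid, offsets, weights, Q, mask, int(fh.attrs["n_dropped"])
        )
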