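"""Speckle contrast forward model.

The exposure-integrated speckle contrast of one detector is

    K^2 = (1/T) int_0^T beta |g1(t)|^2 (1 - t/T) dt,

with the field autocorrelation built from the stored photon ensemble,

    g1(t) = sum_n P_n exp(-2j k0 Y_n t),

where P_n are the per-detector normalized absorption weights and
Y_n = sum_i q_ni v_i the per-photon momentum transfer (um/s here, so that
k0 [um^-1] * Y * t is dimensionless).  Expanding |g1|^2 into photon pairs
and integrating each cosine term exactly gives the closed form

    K^2 = beta * [ 1/2 sum_n P_n^2
                   + sum_{n<m} P_n P_m sin^2(k0 T A_nm) / (k0 T A_nm)^2 ],

with A_nm = Y_n - Y_m; ``contrast_pairwise`` evaluates this (no quadrature
error), ``contrast_quadrature`` integrates |g1|^2 numerically.  As printed
above, the static limit (all A = 0, normalized weights) is K^2 = beta/2;
the factor-of-2 variant found in parts of the LSCI literature is not
applied.  beta defaults to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .phantom import FlowMap
from .transport import BinnedSource, DetectorPhotons, PhotonRecord

__all__ = [
    "ForwardConfig",
    "CorrelationCurve",
    "SpeckleImage",
    "momentum_transfer",
    "g1_curve",
    "contrast_quadrature",
    "contrast_pairwise",
    "forward_image",
    "save_speckle_image",
    "load_speckle_image",
]

MM_S_TO_UM_S = 1000.0


@dataclass(frozen=True)
class ForwardConfig:
    """Exposure/instrumentation parameters of the contrast model.

    T       camera exposure time (s); default 3 ms.
    beta    speckle/detector size-mismatch factor in (0, 1].
    k0      wavenumber (um^-1); default 2*pi/0.785 um (785 nm).
    n_t     quadrature points for the numerical contrast integral.
    """

    T: float = 3e-3
    beta: float = 1.0
    k0: float = 2.0 * np.pi / 0.785
    n_t: int = 200

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("exposure time T must be > 0")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")
        if self.k0 <= 0:
            raise ValueError("k0 must be > 0")
        if self.n_t < 2:
            raise ValueError("need at least 2 quadrature points")

    @property
    def k0T(self) -> float:
        return self.k0 * self.T


@dataclass
class CorrelationCurve:
    """Complex g1 sampled on a lag grid; g1(0) = 1 for normalized weights."""

    t: np.ndarray
    g1: np.ndarray


@dataclass
class SpeckleImage:
    """Per-pixel speckle contrast for one source with a validity mask."""

    K: np.ndarray  # (n, n)
    mask: np.ndarray  # (n, n) bool
    source_id: int
    meta: dict = field(default_factory=dict)

    def valid_values(self) -> np.ndarray:
        return self.K[self.mask]


def momentum_transfer(record: PhotonRecord, flows: FlowMap) -> float:
    """Y_n = sum_i q_ni v_i on the mm/s scale of the flow map.

    Raises ``KeyError`` if the record references a group absent from the
    flow map (inconsistent inputs).
    """
    return float(sum(q * flows[gid] for gid, q in record.q.items()))


def _photon_arrays(det: DetectorPhotons, flows: FlowMap):
    v_um = flows.vector(det.group_ids) * MM_S_TO_UM_S
    Y = det.Q.T.dot(v_um)
    return det.weights, Y


def g1_curve(
    det: DetectorPhotons,
    flows: FlowMap,
    t_grid: np.ndarray,
    k0: float | None = None,
) -> CorrelationCurve:
    """Discretized field autocorrelation g1(t) = sum_n P_n exp(-2j k0 Y_n t)."""
    if det.n_photons == 0:
        raise ValueError("empty detector: no photons to correlate")
    P, Y = _photon_arrays(det, flows)
    if k0 is None:
        k0 = ForwardConfig().k0
    t = np.asarray(t_grid, dtype=np.float64)
    g1 = (P[None, :] * np.exp(-2j * k0 * Y[None, :] * t[:, None])).sum(axis=1)
    return CorrelationCurve(t=t, g1=g1)


def g1_from_Y(P: np.ndarray, Y: np.ndarray, k0: float, t_grid: np.ndarray) -> CorrelationCurve:
    """g1(t) for explicit weights/momentum transfers (Y in um/s)."""
    t = np.asarray(t_grid, dtype=np.float64)
    g1 = (P[None, :] * np.exp(-2j * k0 * Y[None, :] * t[:, None])).sum(axis=1)
    return CorrelationCurve(t=t, g1=g1)


def contrast_quadrature(curve: CorrelationCurve, cfg: ForwardConfig) -> float:
    """K via trapezoid quadrature of (1/T) int beta |g1|^2 (1 - t/T) dt."""
    t = curve.t
    if t[0] > 1e-15 or t[-1] < cfg.T * (1 - 1e-12):
        raise ValueError("lag grid must span [0, T]")
    sel = t <= cfg.T * (1 + 1e-12)
    ts = t[sel]
    integrand = cfg.beta * np.abs(curve.g1[sel]) ** 2 * (1.0 - ts / cfg.T)
    ksq = np.trapezoid(integrand, ts) / cfg.T
    return float(np.sqrt(max(ksq, 0.0)))


def contrast_pairwise(det: DetectorPhotons, flows: FlowMap, cfg: ForwardConfig) -> float:
    """K from the exact pairwise closed form (default forward path)."""
    if det.n_photons == 0:
        raise ValueError("empty detector: no photons")
    P_dyn, Qd, s0, sum_ps2 = det.split_static()
    v_um = flows.vector(det.group_ids) * MM_S_TO_UM_S
    Y_dyn = Qd.T.dot(v_um) if Qd.size else np.zeros(0)
    return float(
        _kernels.pair_contrast(P_dyn, Y_dyn, s0, sum_ps2, cfg.k0T, cfg.beta)
    )


def contrast_pairwise_from_Y(
    P: np.ndarray, Y: np.ndarray, cfg: ForwardConfig
) -> float:
    """Pairwise K for explicit (P, Y) ensembles (Y in um/s)."""
    return float(
        _kernels.pair_contrast(
            np.ascontiguousarray(P, dtype=np.float64),
            np.ascontiguousarray(Y, dtype=np.float64),
            0.0,
            0.0,
            cfg.k0T,
            cfg.beta,
        )
    )


def forward_image(binned: BinnedSource, flows: FlowMap, cfg: ForwardConfig) -> SpeckleImage:
    """Model speckle contrast image for one source at the given flow map."""
    n = binned.grid.n
    K = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    recs = binned.prepared_detectors()
    Y_cat, spans = binned.dyn_momentum(flows.vector(binned.group_ids) * MM_S_TO_UM_S)
    for i, (pixel, _, P_dyn, _, s0, sum_ps2) in enumerate(recs):
        k = _kernels.pair_contrast(
            P_dyn, Y_cat[spans[i] : spans[i + 1]], s0, sum_ps2, cfg.k0T, cfg.beta
        )
        K[pixel // n, pixel % n] = k
        mask[pixel // n, pixel % n] = True
    return SpeckleImage(
        K=K,
        mask=mask,
        source_id=binned.source.source_id,
        meta={
            "T_s": cfg.T,
            "beta": cfg.beta,
            "k0_um": cfg.k0,
            "n_launched": binned.n_launched,
            "mc_seed": binned.seed,
        },
    )


def save_speckle_image(path_prefix: str, image: SpeckleImage) -> None:
    import json

    import tifffile

    tifffile.imwrite(f"{path_prefix}.tif", image.K.astype(np.float32))
    meta = dict(image.meta)
    meta["source_id"] = image.source_id
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    np.save(f"{path_prefix}_mask.npy", image.mask)


def load_speckle_image(path_prefix: str) -> SpeckleImage:
    import json

    import tifffile

    K = tifffile.imread(f"{path_prefix}.tif").astype(np.float64)
    with open(f"{path_prefix}.json") as fh:
        meta = json.load(fh)
    mask = np.load(f"{path_prefix}_mask.npy")
    return SpeckleImage(K=K, mask=mask, source_id=int(meta.pop("source_id")), meta=meta)
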