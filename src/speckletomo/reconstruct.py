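"""Mini-batch proximal gradient reconstruction of the flow map.

Each iteration loops over sources, samples a mini-batch of usable
detectors (with replacement), accumulates the data-misfit gradient over
the batch, and then applies, in order: an Adam step with bias-corrected
moment estimates, the exact TV1D proximal operator along the radius-sorted
group ordering, a Nesterov extrapolation with the t_k = (1+sqrt(1+4 t_{k-1}^2))/2
sequence, and a projection onto V >= 0.  The cumulative batch cost is
recorded; iteration stops when the current batch cost falls below
``e_tol`` (default 0, i.e. run to ``N_iter``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _kernels
from .forward import MM_S_TO_UM_S, ForwardConfig, SpeckleImage
from .phantom import FlowMap, Strand
from .transport import BinnedSource

logger = logging.getLogger(__name__)

__all__ = [
    "ReconConfig",
    "OptimizerState",
    "tv1d_prox",
    "adam_nesterov_step",
    "sample_minibatch",
    "run_reconstruction",
    "group_table",
    "tv_ordering",
    "flow_errors",
]


@dataclass(frozen=True)
class ReconConfig:
    """Optimizer hyperparameters.

    Defaults: Adam (beta1, beta2, eta) = (0.8, 0.999, 0.1), TV weight
    gamma = 1e-3, mini-batch of 1/8 of the usable detectors drawn with
    replacement, at most 200 iterations, e_tol = 0.
    """

    N_iter: int = 200
    batch_fraction: float = 0.125
    gamma: float = 1e-3
    beta1: float = 0.8
    beta2: float = 0.999
    eta: float = 0.1
    eps: float = 1e-8
    e_tol: float = 0.0
    seed: int = 0
    with_replacement: bool = True
    gradient_method: str = "analytic"  # "analytic" | "fd" | "auto"
    fd_eps_rel: float = 1e-6  # FD step relative to the mean flow
    # Cap on the Nesterov extrapolation coefficient (t_{k-1}-1)/t_k.  The
    # uncapped sequence approaches 1 and, combined with Adam's normalized
    # (non-decaying) steps, amplifies iterate displacement without bound;
    # 0 disables the extrapolation (default), 1 restores the uncapped rule.
    nesterov_cap: float = 0.0
    # Detector residual weighting: "photon_count" weights each detector's
    # squared residual by its photon count (inverse-variance weighting for
    # Monte Carlo noise in K, whose variance scales like 1/M); "uniform"
    # weights all usable detectors equally.
    residual_weighting: str = "photon_count"
    # Number of final iterates averaged into the returned flow map (tail
    # averaging damps the stochastic mini-batch jitter of constant-step
    # Adam); 0 returns the last iterate.
    tail_average: int = 40
    # Mini-batch gradient variance reduction: "svrg" subtracts a cached
    # control variate (per-detector gradients at a periodically refreshed
    # anchor iterate, plus the full-batch anchor gradient); "none" uses the
    # plain mini-batch gradient.
    variance_reduction: str = "svrg"
    svrg_anchor_every: int = 40
    # Reset the Adam moment accumulators every this many iterations.  With
    # beta2 = 0.999 the second moment keeps the large early-phase gradients
    # alive for the whole run, collapsing the effective step of coordinates
    # whose gradients have since decayed; periodic restarts re-anchor the
    # moments to the current gradient scale.  None disables restarts.
    moment_restart_every: int | None = 25
    # After this iteration the learning rate anneals as
    # eta / (1 + (k - anneal_after)/anneal_scale); None keeps eta constant.
    eta_anneal_after: int | None = 150
    eta_anneal_scale: float = 8.0
    peripheral_min_photons: int = 50
    v_init: float = 1.0  # mm/s

    def __post_init__(self) -> None:
        if not 0 < self.batch_fraction <= 1:
            raise ValueError("batch_fraction must lie in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("Adam betas must lie in (0, 1)")
        if self.eta <= 0:
            raise ValueError("learning rate eta must be > 0")
        if self.gradient_method not in ("analytic", "fd", "auto"):
            raise ValueError("gradient_method must be analytic, fd or auto")
        if self.residual_weighting not in ("photon_count", "uniform"):
            raise ValueError("residual_weighting must be photon_count or uniform")
        if self.tail_average < 0:
            raise ValueError("tail_average must be >= 0")
        if self.variance_reduction not in ("svrg", "none"):
            raise ValueError("variance_reduction must be svrg or none")
        if self.svrg_anchor_every < 1:
            raise ValueError("svrg_anchor_every must be >= 1")


@dataclass
class OptimizerState:
    """State threaded through ``adam_nesterov_step``."""

    V: np.ndarray  # current iterate (mm/s)
    V_prox_prev: np.ndarray
    m: np.ndarray  # first-moment accumulator
    v: np.ndarray  # second-moment accumulator
    t_k: float = 1.0
    c: float = 0.0  # cumulative batch cost
    k: int = 0
    k_bias: int = 0  # moment bias-correction counter (reset on restarts)

    @classmethod
    def initial(cls, n: int, v_init: float = 1.0) -> "OptimizerState":
        return cls(
            V=np.full(n, float(v_init)),
            V_prox_prev=np.zeros(n),
            m=np.zeros(n),
            v=np.zeros(n),
        )


def tv1d_prox(x: np.ndarray, gamma: float) -> np.ndarray:
    """Exact minimizer of 0.5||u - x||^2 + gamma * TV1D(u) (direct method)."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    x = np.ascontiguousarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    return _kernels.tv1d_denoise(x, float(gamma))


def adam_nesterov_step(
    state: OptimizerState,
    grad: np.ndarray,
    cfg: ReconConfig,
    k: int,
    order: np.ndarray | None = None,
) -> OptimizerState:
    """One optimizer update: Adam -> TV1D prox -> Nesterov -> positivity.

    ``order`` maps the flow vector onto the 1D TV ordering (radius-sorted);
    identity if omitted.  ``k`` is the 1-based iteration counter used for
    Adam bias correction.
    """
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite gradient passed to optimizer")
    if k < 1:
        raise ValueError("iteration counter k must be >= 1")
    k_b = state.k_bias + 1
    m = cfg.beta1 * state.m + (1 - cfg.beta1) * grad
    v = cfg.beta2 * state.v + (1 - cfg.beta2) * grad**2
    m_hat = m / (1 - cfg.beta1**k_b)
    v_hat = v / (1 - cfg.beta2**k_b)
    eta_k = cfg.eta
    if cfg.eta_anneal_after is not None and k > cfg.eta_anneal_after:
        eta_k = cfg.eta / (1.0 + (k - cfg.eta_anneal_after) / cfg.eta_anneal_scale)
    V = state.V - eta_k * m_hat / (np.sqrt(v_hat) + cfg.eps)

    if order is None:
        order = np.arange(len(V))
    V_prox = np.empty_like(V)
    V_prox[order] = tv1d_prox(V[order], cfg.gamma)

    t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * state.t_k**2))
    coeff = min((state.t_k - 1.0) / t_next, cfg.nesterov_cap)
    V_new = V_prox + coeff * (V_prox - state.V_prox_prev)
    np.maximum(V_new, 0.0, out=V_new)

    return replace(
        state, V=V_new, V_prox_prev=V_prox, m=m, v=v, t_k=t_next, k=k, k_bias=k_b
    )


def sample_minibatch(
    n_detectors_total: int,
    fraction: float,
    seed,
    k: int,
    with_replacement: bool = True,
    p: np.ndarray | None = None,
) -> np.ndarray:
    """Reproducible detector sample for iteration ``k``.

    Draws ceil(fraction * N) indices with replacement, optionally with
    per-detector probabilities ``p`` (importance sampling); ``fraction == 1``
    without replacement returns every detector exactly once.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0 and not with_replacement:
        return np.arange(n_detectors_total)
    size = int(np.ceil(fraction * n_detectors_total))
    key = np.atleast_1d(np.asarray(seed, dtype=np.int64))
    rng = np.random.default_rng(np.concatenate([key, [k]]))
    if with_replacement:
        if p is not None:
            return rng.choice(n_detectors_total, size=size, replace=True, p=p)
        return rng.integers(0, n_detectors_total, size=size)
    return rng.permutation(n_detectors_total)[:size]


# ---------------------------------------------------------------------------
# Group bookkeeping
# ---------------------------------------------------------------------------


def group_table(strands: list[Strand]) -> pd.DataFrame:
    """One row per flow group: representative radius, class, depth, orientation."""
    rows = []
    for gid in np.unique([s.group_id for s in strands]):
        members = [s for s in strands if s.group_id == gid]
        rows.append(
            {
                "group_id": int(gid),
                "radius_um": float(np.mean([m.radius for m in members])),
                "tissue_class": members[0].tissue_class,
                "orientation": members[0].orientation,
                "depth_um": float(np.mean([m.depth_um for m in members])),
                "n_strands": len(members),
            }
        )
    return pd.DataFrame(rows).set_index("group_id")


def tv_ordering(groups: pd.DataFrame, group_ids: np.ndarray) -> np.ndarray:
    """Indices that arrange the flow vector for the 1D TV penalty.

    Noncapillary groups sorted by radius (descending, ties by id), then
    capillary groups by id, so the TV chain couples vessels of similar
    caliber.
    """
    info = groups.loc[[int(g) for g in group_ids]]
    is_cap = (info["tissue_class"] == "capillary").to_numpy()
    radius = info["radius_um"].to_numpy()
    keys = [(1, 0.0, int(g)) if c else (0, -r, int(g))
            for c, r, g in zip(is_cap, radius, group_ids)]
    return np.array(sorted(range(len(keys)), key=lambda i: keys[i]), dtype=np.int64)


def dynamic_photon_counts(sources: list[BinnedSource]) -> np.ndarray:
    """Per-group dynamically scattered detected photons across sources."""
    total = None
    for src in sources:
        c = src.dynamic_photon_counts()
        total = c if total is None else total + c
    return total


def flow_errors(
    v_hat: FlowMap,
    v_true: FlowMap,
    groups: pd.DataFrame,
    dyn_counts: np.ndarray | None = None,
    min_photons: int = 50,
) -> pd.DataFrame:
    """Per-group relative error (%) table, flagging peripheral groups.

    Peripheral groups are those sampled by fewer than ``min_photons``
    dynamically scattered detected photons; they are kept in the table but
    marked ``excluded`` for summary statistics.
    """
    gids = v_true.group_ids
    vt = v_true.v
    vh = v_hat.vector(gids)
    err = np.abs(vh - vt) / vt * 100.0
    tab = groups.loc[[int(g) for g in gids]].copy()
    tab["v_true_mm_s"] = vt
    tab["v_hat_mm_s"] = vh
    tab["error_pct"] = err
    if dyn_counts is not None:
        tab["dyn_photons"] = dyn_counts
        tab["excluded"] = dyn_counts < min_photons
    else:
        tab["excluded"] = False
    return tab


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------


def run_reconstruction(
    sources: list[BinnedSource],
    measured: list[SpeckleImage],
    strands: list[Strand],
    cfg: ReconConfig,
    fwd: ForwardConfig | None = None,
    truth: FlowMap | None = None,
    v0: FlowMap | None = None,
) -> tuple[FlowMap, pd.DataFrame]:
    """Recover the per-group flow map from measured speckle images.

    ``sources`` holds the binned reconstruction trajectories (independent
    of the trajectories behind ``measured``); images and sources must share
    the detector grid and be index-aligned by source.  Returns the flow map
    and a per-iteration trace (batch cost and, if ``truth`` is given, the
    median per-group error).
    """
    if fwd is None:
        fwd = ForwardConfig()
    if len(sources) != len(measured):
        raise ValueError("need one measured image per source")
    group_ids = sources[0].group_ids
    G = len(group_ids)
    groups = group_table(strands)
    order = tv_ordering(groups, group_ids)

    # usable detectors: valid pixel in the trajectory set AND in the image mask
    per_source = []
    for src, img in zip(sources, measured):
        if not np.array_equal(src.group_ids, group_ids):
            raise ValueError("sources disagree on flow groups")
        counts = np.diff(src.offsets)
        recs = src.prepared_detectors()
        keep = [i for i, rec in enumerate(recs) if img.mask.ravel()[rec[0]]]
        dets = [recs[i] for i in keep]
        if not dets:
            logger.warning("source %d: all detectors masked; skipping", src.source.source_id)
            continue
        if cfg.residual_weighting == "photon_count":
            det_w = np.array([float(counts[rec[0]]) for rec in dets])
        else:
            det_w = np.ones(len(dets))
        k_meas = img.K.ravel()
        # Stochastic batches realize the weighted cost by importance
        # sampling (draw probability proportional to weight, equal
        # contributions) — same expectation, far lower batch variance than
        # uniform draws with weighted contributions.  Deterministic
        # full-batch sweeps weight contributions explicitly.
        det_p = det_w / det_w.sum()
        per_source.append((src, dets, k_meas, det_w, det_p, np.asarray(keep)))
    if not per_source:
        raise ValueError("no usable detectors in any source")

    method = cfg.gradient_method
    if method == "auto":
        method = "fd" if G <= 60 else "analytic"

    state = OptimizerState.initial(G, cfg.v_init)
    if v0 is not None:
        state.V = v0.vector(group_ids).astype(np.float64).copy()

    stochastic = cfg.with_replacement and cfg.batch_fraction < 1.0
    use_svrg = cfg.variance_reduction == "svrg" and stochastic
    sum_w = sum(float(t[3].sum()) for t in per_source)

    def det_gradient(src_tuple, di, Y_cat, spans, eps_um):
        _, dets, k_meas, _, _, prep_idx = src_tuple
        pixel, _, P_dyn, Qd, s0, sum_ps2 = dets[di]
        pi = prep_idx[di]
        Y_dyn = Y_cat[spans[pi] : spans[pi + 1]]
        if method == "analytic":
            _, res, g_um = _kernels.pair_residual_grad_analytic(
                P_dyn, Y_dyn, Qd, s0, sum_ps2, fwd.k0T, fwd.beta, k_meas[pixel]
            )
        else:
            _, res, g_um = _kernels.pair_residual_grad_fd(
                P_dyn, Y_dyn, Qd, s0, sum_ps2, fwd.k0T, fwd.beta,
                k_meas[pixel], eps_um,
            )
        return res, g_um

    anchor_grads: list[np.ndarray] | None = None
    anchor_full = np.zeros(G)

    def refresh_anchor(v_mm, eps_um):
        """Full weighted gradient and per-detector gradients at the anchor."""
        nonlocal anchor_grads, anchor_full
        anchor_grads = []
        anchor_full = np.zeros(G)
        for src_tuple in per_source:
            src, dets, _, det_w, _, _ = src_tuple
            Y_cat, spans = src.dyn_momentum(v_mm * MM_S_TO_UM_S)
            ga = np.empty((len(dets), G))
            for di in range(len(dets)):
                _, g_um = det_gradient(src_tuple, di, Y_cat, spans, eps_um)
                ga[di] = g_um
                anchor_full += det_w[di] * g_um
            anchor_grads.append(ga)

    trace = []
    tail: list[np.ndarray] = []
    for k in range(1, cfg.N_iter + 1):
        eps_um = cfg.fd_eps_rel * max(float(state.V.mean()), 1e-12) * MM_S_TO_UM_S
        if use_svrg and (k - 1) % cfg.svrg_anchor_every == 0:
            refresh_anchor(state.V.copy(), eps_um)
        grad = np.zeros(G)
        batch_cost = 0.0
        n_batch = 0
        for j, src_tuple in enumerate(per_source):
            src, dets, k_meas, det_w, det_p, _ = src_tuple
            Y_cat, spans = src.dyn_momentum(state.V * MM_S_TO_UM_S)
            ids = sample_minibatch(
                len(dets), cfg.batch_fraction, (cfg.seed, j), k,
                cfg.with_replacement, p=det_p if stochastic else None,
            )
            for di in ids:
                res, g_um = det_gradient(src_tuple, di, Y_cat, spans, eps_um)
                if use_svrg:
                    grad += g_um - anchor_grads[j][di]
                elif stochastic:
                    grad += g_um
                else:
                    grad += det_w[di] * g_um
                batch_cost += (1.0 if stochastic else det_w[di]) * res
            n_batch += len(ids)
        if use_svrg:
            grad = anchor_full + (sum_w / n_batch) * grad
        grad *= MM_S_TO_UM_S  # per mm/s
        if cfg.moment_restart_every and (k - 1) % cfg.moment_restart_every == 0:
            state.m[:] = 0.0
            state.v[:] = 0.0
            state.k_bias = 0
        state = adam_nesterov_step(state, grad, cfg, k, order)
        state.c += batch_cost
        if cfg.tail_average:
            tail.append(state.V.copy())
            if len(tail) > cfg.tail_average:
                tail.pop(0)
        row = {"iteration": k, "batch_cost": batch_cost}
        if truth is not None:
            vh = FlowMap(group_ids=group_ids, v=state.V.copy())
            row["median_error_pct"] = float(
                np.median(np.abs(vh.vector(truth.group_ids) - truth.v) / truth.v * 100.0)
            )
        trace.append(row)
        if k % 25 == 0 or k == 1:
            logger.info("iter %d: batch cost %.3e", k, batch_cost)
        if batch_cost < cfg.e_tol:
            logger.info("stopping at iteration %d: batch cost below e_tol", k)
            break

    if tail:
        stack = np.stack(tail)
        # averaging identical iterates must not perturb an exact fixed point
        v_out = stack[0] if np.all(stack == stack[0]) else stack.mean(axis=0)
    else:
        v_out = state.V
    flows = FlowMap(group_ids=group_ids, v=v_out.copy())
    return flows, pd.DataFrame(trace)
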