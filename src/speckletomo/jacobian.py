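"""Gradients of the per-detector data misfit w.r.t. per-group flows.

For one detector the residual is r = (K_meas - Khat(V))^2, with Khat the
pairwise closed-form contrast of the stored photon ensemble.  Two routes
are provided:

* ``analytic_gradient`` differentiates the pair sum exactly: each pair
  (n, m) contributes
      d Khat^2 / d v_i = beta k0 T * P_n P_m (q_ni - q_mi)
                         * 2 sin(x) (x cos x - sin x) / x^3,    x = k0 T A,
  with A = Y_n - Y_m; the chain rule through Khat = sqrt(Khat^2) supplies
  the (K/Khat - 1)-type prefactor of the squared residual.
* ``fd_gradient`` perturbs each group flow by a forward difference eps and
  re-evaluates the same stored-trajectory forward (a perturbation of the
  fixed Monte Carlo trajectories, not a new simulation): all partials come
  from one unperturbed plus G perturbed evaluations.

Gradient components of groups never sampled by the detector's photons are
exactly zero on both routes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .forward import MM_S_TO_UM_S, ForwardConfig
from .phantom import FlowMap
from .transport import DetectorPhotons

__all__ = ["GradientVector", "analytic_gradient", "fd_gradient"]


@dataclass
class GradientVector:
    """Partials of the squared residual w.r.t. group flows (per mm/s)."""

    group_ids: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.d)):
            raise FloatingPointError("non-finite gradient")


def _det_arrays(det: DetectorPhotons, flows: FlowMap):
    P_dyn, Qd, s0, sum_ps2 = det.split_static()
    v_um = flows.vector(det.group_ids) * MM_S_TO_UM_S
    Y_dyn = Qd.T.dot(v_um) if Qd.size else np.zeros(0)
    return P_dyn, Y_dyn, Qd, s0, sum_ps2


def analytic_gradient(
    det: DetectorPhotons, flows: FlowMap, k_measured: float, cfg: ForwardConfig
) -> GradientVector:
    """Gradient of (K_meas - Khat)^2 by the analytic pairwise formula."""
    P_dyn, Y_dyn, Qd, s0, sum_ps2 = _det_arrays(det, flows)
    khat, _, grad_um = _kernels.pair_residual_grad_analytic(
        P_dyn, Y_dyn, Qd, s0, sum_ps2, cfg.k0T, cfg.beta, k_measured
    )
    if khat <= 0.0:
        raise ZeroDivisionError("Khat = 0: residual prefactor undefined")
    return GradientVector(group_ids=det.group_ids, d=grad_um * MM_S_TO_UM_S)


def fd_gradient(
    det: DetectorPhotons,
    flows: FlowMap,
    k_measured: float,
    eps: float,
    cfg: ForwardConfig,
) -> GradientVector:
    """Gradient of (K_meas - Khat)^2 by vectorized forward differences.

    ``eps`` is the flow perturbation in mm/s (typically 1e-6 x mean flow).
    """
    if eps <= 0:
        raise ValueError("finite-difference step eps must be > 0")
    P_dyn, Y_dyn, Qd, s0, sum_ps2 = _det_arrays(det, flows)
    _, _, grad_um = _kernels.pair_residual_grad_fd(
        P_dyn, Y_dyn, Qd, s0, sum_ps2, cfg.k0T, cfg.beta, k_measured, eps * MM_S_TO_UM_S
    )
    return GradientVector(group_ids=det.group_ids, d=grad_um * MM_S_TO_UM_S)
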