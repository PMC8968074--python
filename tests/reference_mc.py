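"""Deliberately naive reference Monte Carlo for cross-validation.

Independent of the package's voxel transport: homogeneous box, direct
free-path sampling (no voxel stepping, no empty-space skipping), its own
linear-congruential RNG, and discrete-albedo weighting instead of
continuous path-length absorption.  Only the physics (HG scattering,
index-matched boundaries, top-surface detection) is shared, so agreement
of the diffuse reflectance is a meaningful check.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def naive_box_reflectance(n_photons, seed, lx, ly, lz, mu_a, mu_s, g,
                          src_x, src_y, max_events=100000):
    """Total top-surface diffuse reflectance of a homogeneous box.

    Coefficients in um^-1, box dimensions in um.  Returns (sum of detected
    weights, sum of squared detected weights) for standard-error estimates.
    """
    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t
    state = np.uint64(seed * 2654435761 + 1)
    total = 0.0
    total_sq = 0.0
    for _ in range(n_photons):
        x = src_x
        y = src_y
        z = 1e-9
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        for _ev in range(max_events):
            # LCG (MMIX constants)
            state = np.uint64(state * np.uint64(6364136223846793005) + np.uint64(1442695040888963407))
            u = (state >> np.uint64(11)) * (1.0 / 9007199254740992.0)
            s = -math.log(u + 1e-300) / mu_t
            x += ux * s
            y += uy * s
            z += uz * s
            if z < 0.0:
                # escape through the top: credit the current weight
                f = z / uz
                ex = x - ux * f
                ey = y - uy * f
                if 0.0 <= ex < lx and 0.0 <= ey < ly:
                    total += w
                    total_sq += w * w
                break
            if x < 0.0 or x >= lx or y < 0.0 or y >= ly or z >= lz:
                break
            w *= albedo
            if w < 1e-4:
                state = np.uint64(state * np.uint64(6364136223846793005) + np.uint64(1442695040888963407))
                u = (state >> np.uint64(11)) * (1.0 / 9007199254740992.0)
                if u < 0.1:
                    w /= 0.1
                else:
                    break
            # HG scatter
            state = np.uint64(state * np.uint64(6364136223846793005) + np.uint64(1442695040888963407))
            u = (state >> np.uint64(11)) * (1.0 / 9007199254740992.0)
            if abs(g) < 1e-6:
                ct = 1.0 - 2.0 * u
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                ct = min(1.0, max(-1.0, ct))
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            state = np.uint64(state * np.uint64(6364136223846793005) + np.uint64(1442695040888963407))
            u = (state >> np.uint64(11)) * (1.0 / 9007199254740992.0)
            phi = 2.0 * math.pi * u
            cp = math.cos(phi)
            sp = math.sin(phi)
            if abs(uz) > 0.99999:
                nx_, ny_, nz_ = st * cp, st * sp, ct * (1.0 if uz >= 0 else -1.0)
            else:
                den = math.sqrt(1.0 - uz * uz)
                nx_ = st * (ux * uz * cp - uy * sp) / den + ux * ct
                ny_ = st * (uy * uz * cp + ux * sp) / den + uy * ct
                nz_ = -st * cp * den + uz * ct
            norm = math.sqrt(nx_ * nx_ + ny_ * ny_ + nz_ * nz_)
            ux, uy, uz = nx_ / norm, ny_ / norm, nz_ / norm
    return total, total_sq
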