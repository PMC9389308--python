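"""LMS (Box-Cox) standardization math.

The LMS method summarizes an age-varying measurement distribution by three
curves — a Box-Cox power L(age), a median M(age) and a coefficient of
variation S(age) — chosen so that

    z = ((x/M)^L - 1) / (L * S)      for L != 0
    z = ln(x/M) / S                  for L == 0

is approximately standard normal.  This module implements the forward and
inverse transforms, the z <-> centile conversion through the standard normal
CDF, BMI, and a linearized fallback score built from the 50th and 3rd
centile curves alone (for references published without L/M/S columns).

All functions are pure, accept scalars or numpy arrays, and raise
``ValueError`` on domain violations.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "EPS_L",
    "lms_z",
    "lms_value",
    "z_to_centile",
    "centile_to_z",
    "approx_sds",
    "bmi",
]

#: |L| below this is treated as the log-normal limit L -> 0.  Well below any
#: tabulated L resolution, well above double-precision noise.
EPS_L = 1e-7


def _validate_positive(**named):
    for name, value in named.items():
        arr = np.asarray(value, dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


def lms_z(x, L, M, S):
    """Standard deviation score (SDS) of measurement ``x`` under (L, M, S).

    Parameters
    ----------
    x : measurement in the reference's units (> 0)
    L : Box-Cox power (dimensionless)
    M : reference median, same units as ``x`` (> 0)
    S : coefficient of variation (> 0)

    Returns
    -------
    z : float or ndarray
        The SDS; 0 when ``x == M``.  Continuous in L across L = 0.
    """
    _validate_positive(x=x, M=M, S=S)
    x, L, M, S = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (x, L, M, S))
    )
    ratio = x / M
    with np.errstate(divide="ignore", invalid="ignore"):
        z_boxcox = (np.power(ratio, L) - 1.0) / (L * S)
    z_log = np.log(ratio) / S
    z = np.where(np.abs(L) < EPS_L, z_log, z_boxcox)
    return z if z.ndim else float(z)


def lms_value(z, L, M, S):
    """Inverse LMS transform: the measurement lying ``z`` SDS from the median.

    Requires ``1 + L*S*z > 0`` when ``|L| >= EPS_L`` (the Box-Cox power
    argument must stay positive); otherwise raises ``ValueError``.
    Satisfies ``lms_z(lms_value(z, L, M, S), L, M, S) == z`` to 1e-9.
    """
    _validate_positive(M=M, S=S)
    z, L, M, S = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (z, L, M, S))
    )
    arg = 1.0 + L * S * z
    boxcox_branch = np.abs(L) >= EPS_L
    if np.any(boxcox_branch & (arg <= 0)):
        raise ValueError(
            "inverse LMS undefined: 1 + L*S*z <= 0 "
            f"(min argument {np.min(arg[boxcox_branch]):.6g})"
        )
    safe_L = np.where(boxcox_branch, L, 1.0)
    safe_arg = np.where(boxcox_branch, arg, 1.0)
    x_boxcox = M * np.power(safe_arg, 1.0 / safe_L)
    x_log = M * np.exp(S * z)
    x = np.where(boxcox_branch, x_boxcox, x_log)
    return x if x.ndim else float(x)


def z_to_centile(z):
    """Map an SDS to a centile in percent via the standard normal CDF."""
    z = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(z)):
        raise ValueError("z must be finite")
    c = 100.0 * stats.norm.cdf(z)
    return c if c.ndim else float(c)

def centile_to_z(p):
    """Map a centile in percent (open interval (0, 100)) to an SDS."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 100)):
        raise ValueError(f"centile must lie strictly between 0 and 100, got {p!r}")
    z = stats.norm.ppf(p / 100.0)
    return z if z.ndim else float(z)


def approx_sds(x, p50, p3):
    """Linearized SDS from the 50th and 3rd centile curves alone.

    ``(x - P50) / (0.5 * (P50 - P3))`` — zero at the median, −2 at the 3rd
    centile by construction.  Because the exact SDS at the 3rd centile is
    Φ⁻¹(0.03) ≈ −1.8808, this fallback overstates |SDS| by a factor
    2/1.8808 ≈ 1.063 there; prefer :func:`lms_z` whenever L/M/S are known.
    """
    x, p50, p3 = (np.asarray(v, dtype=float) for v in np.broadcast_arrays(x, p50, p3))
    if np.any(p3 >= p50):
        raise ValueError("P3 must lie strictly below P50")
    out = (x - p50) / (0.5 * (p50 - p3))
    return out if out.ndim else float(out)


def bmi(weight_kg, height_m):
    """Body mass index, weight (kg) / height (m) squared."""
    _validate_positive(weight_kg=weight_kg, height_m=height_m)
    out = np.asarray(weight_kg, dtype=float) / np.asarray(height_m, dtype=float) ** 2
    return out if out.ndim else float(out)
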