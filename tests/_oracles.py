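"""Independent oracles used by the test suite.

These are deliberately separate implementations from the package code:
an independently coded A1 visual-pigment template (Govardovskii-type
rational-exponential form, a different published closed form than the
package's modified log-Gaussian) and closed-form results for the logistic
transmittance step.
"""

from __future__ import annotations

import numpy as np


def govardovskii_a1(lambda_max_nm: float, wavelengths_nm) -> np.ndarray:
    """Govardovskii-type A1 alpha-band template (independent closed form).

    S(lambda) = 1 / (exp(A(a-x)) + exp(B(b-x)) + exp(C(c-x)) + D) with
    x = lambda_max / lambda, A=69.7, B=28, C=-14.9, D=0.674, b=0.922,
    c=1.104 and a = 0.8795 + 0.0459*exp(-(lambda_max-300)^2 / 11940).
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    x = lambda_max_nm / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max_nm - 300.0) ** 2) / 11940.0)
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    return 1.0 / (
        np.exp(A * (a - x)) + np.exp(B * (0.922 - x)) + np.exp(C * (1.104 - x)) + D
    )


def logistic_T(wavelengths_nm, midpoint_nm: float, scale_nm: float,
               T_hi: float = 100.0, T_lo: float = 0.0) -> np.ndarray:
    """Logistic transmittance step used as an analytic test input."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    return T_lo + (T_hi - T_lo) / (1.0 + np.exp(-(wl - midpoint_nm) / scale_nm))


def logistic_tangent_intercept(midpoint_nm: float, scale_nm: float,
                               T_hi: float = 100.0, T_lo: float = 0.0) -> float:
    """Closed-form x-intercept of the tangent at the point of steepest slope.

    Max slope is at the midpoint m, where T = (T_hi+T_lo)/2 and
    T' = (T_hi-T_lo)/(4s), so the tangent crosses zero transmittance at
    m - 2s(T_hi+T_lo)/(T_hi-T_lo); for T_lo = 0 this is m - 2s.
    """
    return midpoint_nm - 2.0 * scale_nm * (T_hi + T_lo) / (T_hi - T_lo)
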