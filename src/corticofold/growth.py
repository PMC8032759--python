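"""Temporal cortical growth laws and the tangential growth tensor.

The cortex is modelled as growing tangentially relative to the underlying
white matter.  A growth law alpha(t) on model time t in [0, 1] sets the
magnitude of cumulative tangential expansion; the local expansion ratio g
decays from 1 + alpha at the surface to 1 at depth through a sigmoid of the
material depth y measured in units of the initial cortical thickness H_i;
and the growth tensor G = g*I + (1 - g) * n (x) n expands each tetrahedron
tangentially about its material surface normal n (eigenvalues g, g, 1, so
det G = g^2: areal growth only).

Model time maps to gestational age through a fixed cubic: t = 0 is about
22 gestational weeks and t = 1 the adult brain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LINEAR_COEFFICIENT",
    "GrowthLaw",
    "alpha",
    "ga_to_t",
    "tangential_ratio",
    "growth_tensor",
    "DEFAULT_LAWS",
]

# Linear law coefficient sqrt(8) - 1 = 1.8284...; chosen so the surface areal
# growth factor at t = 1 is g^2 = (1 + alpha)^2 ~= 8.
LINEAR_COEFFICIENT = np.sqrt(8.0) - 1.0


@dataclass(frozen=True)
class GrowthLaw:
    """Tagged growth-law parameterization.

    kind:
      * ``linear``   alpha = (sqrt(8) - 1) * t, no free parameters
      * ``gompertz`` alpha = a * exp(-exp(-b (t - c)))
      * ``logistic`` alpha = a / (1 + exp(-b (t - c)))

    ``a`` is the asymptote / maximum (dimensionless), ``b`` the rate and
    ``c`` the time shift.
    """

    kind: str
    a: float = LINEAR_COEFFICIENT
    b: float = 0.0
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "gompertz", "logistic"):
            raise ValueError(f"unknown growth-law kind: {self.kind!r}")
        if self.a <= 0:
            raise ValueError("growth-law amplitude a must be positive")

    def __call__(self, t):
        return alpha(self, t)

    @classmethod
    def linear(cls) -> "GrowthLaw":
        return cls("linear")

    @classmethod
    def gompertz(cls, b: float = 6.6, c: float = 0.43,
                 a: float = LINEAR_COEFFICIENT) -> "GrowthLaw":
        return cls("gompertz", a=a, b=b, c=c)

    @classmethod
    def logistic(cls, b: float = 50.0, c: float = 0.9,
                 a: float = LINEAR_COEFFICIENT) -> "GrowthLaw":
        return cls("logistic", a=a, b=b, c=c)

    @property
    def label(self) -> str:
        if self.kind == "linear":
            return "linear"
        return f"{self.kind}(b={self.b:g},c={self.c:g})"

    def to_dict(self) -> dict:
        return {"kind": self.kind, "a": self.a, "b": self.b, "c": self.c}

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthLaw":
        kind = d["kind"]
        if kind == "linear":
            return cls.linear()
        return cls(kind, a=float(d.get("a", LINEAR_COEFFICIENT)),
                   b=float(d["b"]), c=float(d["c"]))


# The two Gompertz parameterizations and the late-logistic mode compared
# against the linear law, all sharing the asymptote sqrt(8) - 1.
DEFAULT_LAWS: tuple[GrowthLaw, ...] = (
    GrowthLaw.linear(),
    GrowthLaw.gompertz(6.6, 0.43),
    GrowthLaw.gompertz(7.5, 0.19),
    GrowthLaw.logistic(50.0, 0.9),
)


def alpha(law: GrowthLaw, t):
    """Cumulative tangential growth alpha(t) for t in [0, 1]."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0) or np.any(t > 1.0):
        raise ValueError("model time t must lie within [0, 1]")
    if law.kind == "linear":
        out = LINEAR_COEFFICIENT * t
    elif law.kind == "gompertz":
        out = law.a * np.exp(-np.exp(-law.b * (t - law.c)))
    else:  # logistic
        out = law.a / (1.0 + np.exp(-law.b * (t - law.c)))
    return float(out) if out.ndim == 0 else out


# Cubic mapping gestational age (weeks) to model time, clipped to [0, 1].
_GA_COEFFS = (6.926e-5, -0.00665, 0.250, -3.0189)


def ga_to_t(ga_weeks):
    """Model time for a gestational age in weeks (>= 22)."""
    ga = np.asarray(ga_weeks, dtype=float)
    if np.any(ga < 22.0):
        raise ValueError("gestational age must be >= 22 weeks")
    c3, c2, c1, c0 = _GA_COEFFS
    t = ((c3 * ga + c2) * ga + c1) * ga + c0
    t = np.clip(t, 0.0, 1.0)
    return float(t) if t.ndim == 0 else t


def tangential_ratio(y, H_i: float, alpha_t: float):
    """Local tangential expansion ratio g = 1 + alpha / (1 + e^{10(y/H - 1)}).

    ``y`` is the material depth below the surface and ``H_i`` the initial
    cortical thickness, in the same (normalized) units.  g ranges from
    ~1 + alpha in the cortical layer to ~1 in the deep white matter.
    """
    if H_i <= 0:
        raise ValueError("initial cortical thickness H_i must be positive")
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("material depth y must be nonnegative")
    arg = np.clip(10.0 * (y / H_i - 1.0), -500.0, 500.0)
    g = 1.0 + alpha_t / (1.0 + np.exp(arg))
    return float(g) if g.ndim == 0 else g


def growth_tensor(g: float, n_hat: np.ndarray, tol: float = 1e-3) -> np.ndarray:
    """Tangential growth tensor G = g*I + (1 - g) * n (x) n.

    G expands by g in the two directions perpendicular to the unit normal
    ``n_hat`` and leaves the normal direction unchanged (G n = n, det G =
    g^2).  A normal off unit length by more than ``tol`` is an error; within
    ``tol`` it is renormalized with a warning.
    """
    n = np.asarray(n_hat, dtype=float)
    norm = np.linalg.norm(n)
    if abs(norm - 1.0) > 1e-8:
        if abs(norm - 1.0) > tol or norm == 0:
            raise ValueError(f"n_hat must be a unit vector (|n| = {norm:.6g})")
        import warnings

        warnings.warn(f"renormalizing near-unit normal (|n| = {norm:.6g})")
        n = n / norm
    return g * np.eye(3) + (1.0 - g) * np.outer(n, n)
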