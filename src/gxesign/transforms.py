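"""Monotone outcome transformations with convexity metadata.

A linear interaction test is scale-dependent: re-expressing the outcome
through a monotone map ``phi`` can create or destroy G×E terms, and for
globally convex (or concave) maps the *direction* of the induced
interaction is determined by the signs of the main effects together with
``sgn(phi'')``.  This module is the registry of such maps.  Each entry
records, besides the callable itself, the metadata the sign theory needs:
the domain, the monotonicity direction and the sign of the second
derivative (or ``"mixed"`` for maps such as the logistic whose curvature
changes sign across the domain and which are therefore outside the
analytic rule).

Affine shifts of the input do not change curvature, so maps with
restricted support (log, sqrt, square) can be applied to arbitrary real
outcomes after a positivity shift; :class:`ShiftPolicy` makes the shift
explicit and reproducible.

The rank-based inverse normal transformation (INT) is also provided.  It
is monotone but data-dependent and non-convex, so it carries no
:class:`TransformSpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "TransformSpec",
    "ShiftPolicy",
    "MIXED",
    "make_transform",
    "apply_transform",
    "inverse_normal_transform",
    "registry_names",
]

#: Curvature marker for piecewise-convex maps (logistic, tanh).  These are
#: excluded from the analytic sign rule; only the numeric oracle handles them.
MIXED = "mixed"


@dataclass(frozen=True)
class TransformSpec:
    """A monotone map with its sign-theory metadata.

    Attributes
    ----------
    name : str
        Registry name.
    params : dict
        Parameters the map was built with (e.g. logistic center ``x0``).
    domain_low, domain_high : float
        Extended-real domain bounds.
    domain_low_open : bool
        Whether the lower bound is excluded (log requires ``x > 0``;
        sqrt admits ``x = 0``).
    monotone_sign : int
        +1 increasing, -1 decreasing on the domain.
    curvature_sign : int | str
        ``sgn(phi'')`` on the domain: +1, 0, -1, or :data:`MIXED`.
    """

    name: str
    params: dict = field(default_factory=dict)
    domain_low: float = -math.inf
    domain_high: float = math.inf
    domain_low_open: bool = False
    monotone_sign: int = 1
    curvature_sign: int | str = 0
    func: Callable[[np.ndarray], np.ndarray] = field(default=None, repr=False, compare=False)
    second_deriv: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __call__(self, x):
        return self.func(np.asarray(x, dtype=float))

    def in_domain(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo = x > self.domain_low if self.domain_low_open else x >= self.domain_low
        return lo & (x <= self.domain_high)


@dataclass(frozen=True)
class ShiftPolicy:
    """Affine pre-shift applied before a transform with restricted support.

    ``to_positive`` shifts so that ``min(y) == margin > 0``; ``fixed`` adds a
    user-chosen offset; ``none`` applies no shift (domain violations then
    raise).  A shift is affine, hence preserves both monotonicity and
    ``sgn(phi'')`` of the composed map.
    """

    mode: str = "none"  # none | to_positive | fixed
    offset: float = 0.0
    margin: float = 1.0

    def __post_init__(self):
        if self.mode not in ("none", "to_positive", "fixed"):
            raise ValueError(f"unknown shift mode {self.mode!r}")
        if self.mode == "to_positive" and not self.margin > 0:
            raise ValueError("to_positive margin must be > 0")

    def resolve(self, y: np.ndarray) -> float:
        """Offset actually applied to ``y`` under this policy."""
        if self.mode == "none":
            return 0.0
        if self.mode == "fixed":
            return float(self.offset)
        return float(self.margin - np.min(y))


def _sgn(v: float) -> int:
    return (v > 0) - (v < 0)


def _build_log(params):
    return TransformSpec(
        "log", params, 0.0, math.inf, True, 1, -1,
        func=np.log, second_deriv=lambda x: -1.0 / x**2,
    )


def _build_exp(params):
    return TransformSpec("exp", params, -math.inf, math.inf, False, 1, 1,
                         func=np.exp, second_deriv=np.exp)


def _build_neg_exp(params):
    # e^{-x}: decreasing, phi'' = e^{-x} > 0
    return TransformSpec("neg_exp", params, -math.inf, math.inf, False, -1, 1,
                         func=lambda x: np.exp(-x), second_deriv=lambda x: np.exp(-x))


def _build_square(params):
    # x^2 restricted to x >= 0, where it is increasing and convex
    return TransformSpec("square", params, 0.0, math.inf, False, 1, 1,
                         func=np.square, second_deriv=lambda x: np.full_like(x, 2.0))


def _build_neg_square(params):
    return TransformSpec("neg_square", params, 0.0, math.inf, False, -1, -1,
                         func=lambda x: -np.square(x),
                         second_deriv=lambda x: np.full_like(x, -2.0))


def _build_sqrt(params):
    return TransformSpec("sqrt", params, 0.0, math.inf, False, 1, -1,
                         func=np.sqrt, second_deriv=lambda x: -0.25 * x**-1.5)


def _build_power(params):
    k = float(params.get("exponent", 2.0))
    if not math.isfinite(k) or k == 0:
        raise ValueError("power exponent must be finite and nonzero")
    curv = _sgn(k * (k - 1.0))
    mono = 1 if k > 0 else -1
    return TransformSpec(
        "power", {"exponent": k}, 0.0, math.inf, True, mono, curv,
        func=lambda x: x**k,
        second_deriv=lambda x: k * (k - 1.0) * x ** (k - 2.0),
    )


def _build_boxcox(params):
    lam = float(params.get("lmbda", 0.0))
    if not math.isfinite(lam):
        raise ValueError("Box-Cox exponent must be finite")
    if lam == 0.0:
        spec = _build_log({})
        return TransformSpec("boxcox", {"lmbda": 0.0}, 0.0, math.inf, True, 1, -1,
                             func=spec.func, second_deriv=spec.second_deriv)
    return TransformSpec(
        "boxcox", {"lmbda": lam}, 0.0, math.inf, True, 1, _sgn(lam - 1.0),
        func=lambda x: (x**lam - 1.0) / lam,
        second_deriv=lambda x: (lam - 1.0) * x ** (lam - 2.0),
    )


def _build_logistic(params):
    x0 = float(params.get("x0", 0.0))

    def f(x):
        return stats.logistic.cdf(x, loc=x0)

    def d2(x):
        s = f(x)
        return s * (1.0 - s) * (1.0 - 2.0 * s)

    return TransformSpec("logistic", {"x0": x0}, -math.inf, math.inf, False, 1, MIXED,
                         func=f, second_deriv=d2)


def _build_tanh(params):
    x0 = float(params.get("x0", 0.0))
    return TransformSpec(
        "tanh", {"x0": x0}, -math.inf, math.inf, False, 1, MIXED,
        func=lambda x: np.tanh(x - x0),
        second_deriv=lambda x: -2.0 * np.tanh(x - x0) / np.cosh(x - x0) ** 2,
    )


def _build_identity(params):
    return TransformSpec("identity", {}, -math.inf, math.inf, False, 1, 0,
                         func=lambda x: x + 0.0,
                         second_deriv=lambda x: np.zeros_like(x))


def _build_affine(params):
    a = float(params.get("slope", 1.0))
    b = float(params.get("intercept", 0.0))
    if a == 0:
        raise ValueError("affine slope must be nonzero (map would not be monotone)")
    return TransformSpec("affine", {"slope": a, "intercept": b},
                         -math.inf, math.inf, False, _sgn(a), 0,
                         func=lambda x: a * x + b,
                         second_deriv=lambda x: np.zeros_like(x))


_REGISTRY: dict[str, Callable[[dict], TransformSpec]] = {
    "log": _build_log,
    "exp": _build_exp,
    "neg_exp": _build_neg_exp,
    "square": _build_square,
    "neg_square": _build_neg_square,
    "sqrt": _build_sqrt,
    "power": _build_power,
    "boxcox": _build_boxcox,
    "logistic": _build_logistic,
    "tanh": _build_tanh,
    "identity": _build_identity,
    "affine": _build_affine,
}


def registry_names() -> list[str]:
    return sorted(_REGISTRY)


def make_transform(name: str, **params) -> TransformSpec:
    """Build a registered transform by name.

    Examples
    --------
    >>> make_transform("log").curvature_sign
    -1
    >>> make_transform("logistic", x0=7.0).curvature_sign
    'mixed'
    """
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown transform {name!r}; available: {', '.join(registry_names())}"
        ) from None
    return builder(params)


def apply_transform(
    y: np.ndarray, spec: TransformSpec, shift: ShiftPolicy | None = None
) -> tuple[np.ndarray, float]:
    """Apply ``spec`` element-wise after resolving the shift policy.

    Returns the transformed vector together with the offset actually
    applied, so that a per-replicate ``to_positive`` shift is reproducible
    from the report alone.  A domain violation after shifting is a hard
    error, never a silent NaN.
    """
    y = np.asarray(y, dtype=float)
    shift = shift or ShiftPolicy()
    offset = shift.resolve(y)
    shifted = y + offset
    bad = ~spec.in_domain(shifted)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"value {shifted[i]:g} (index {i}) outside domain of {spec.name!r} "
            f"after shift {offset:g}; use a ShiftPolicy that maps data into "
            f"({'(' if spec.domain_low_open else '['}{spec.domain_low:g}, {spec.domain_high:g}]"
        )
    return spec.func(shifted), offset


def inverse_normal_transform(y: np.ndarray, offset_constant: float = 0.5) -> np.ndarray:
    """Rank-based inverse normal transformation.

    Maps the empirical quantiles of ``y`` onto standard-normal quantiles:
    ``z_i = Phi^{-1}((r_i - c) / (n - 2c + 1))`` with averaged ranks for
    ties and the Blom-type constant ``c`` (default 0.5).  Rank order is
    preserved exactly, including tie groups; distances are not, which is
    why INT carries no convexity metadata and is handled outside the
    analytic sign rule.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("inverse_normal_transform needs a 1-d vector with n >= 2")
    if not 0.0 <= offset_constant <= 0.5:
        raise ValueError("offset_constant must lie in [0, 0.5]")
    if np.all(y == y[0]):
        raise ValueError("all input values are equal; ranks are degenerate")
    ranks = stats.rankdata(y, method="average")
    n = y.size
    return stats.norm.ppf((ranks - offset_constant) / (n - 2.0 * offset_constant + 1.0))
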