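"""First-order propagation of measurement uncertainty.

Plaque-assay quantities (titers in PFU/mL, efficiencies of plating, class
fractions) are carried as ``value +/- sd`` pairs.  Binary operations assume
independent errors and propagate standard deviations by the first-order
Taylor rule, the standard convention for hand-combined plating data.  A
one-sided detection bound (e.g. a titer "< 1e4 PFU/mL" from an all-zero
dilution series) lives on the same type via the ``bound`` flag so that
ratios built from it stay flagged as bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "UncertainValue",
    "uv",
    "uv_ratio",
    "uv_product",
    "uv_sum",
    "uv_scale",
]


@dataclass(frozen=True)
class UncertainValue:
    """A measured quantity with a standard deviation.

    Parameters
    ----------
    value : float
        Central value, in assay units.
    sd : float
        Standard deviation, same units; must be >= 0.
    bound : {None, "upper", "lower"}
        If set, ``value`` is a one-sided bound (detection limit) rather
        than a point estimate.
    note : str
        Free-text provenance (e.g. ``"below detection"``).
    """

    value: float
    sd: float = 0.0
    bound: str | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.bound not in (None, "upper", "lower"):
            raise ValueError(f"bound must be None/'upper'/'lower', got {self.bound!r}")

    # -- helpers -----------------------------------------------------------
    @property
    def rel_sd(self) -> float:
        """Relative standard deviation; inf for a zero central value with sd > 0."""
        if self.value == 0:
            return math.inf if self.sd > 0 else 0.0
        return abs(self.sd / self.value)

    @property
    def is_bound(self) -> bool:
        return self.bound is not None

    def flagged(self, note: str, bound: str | None = None) -> "UncertainValue":
        return replace(self, note=note, bound=bound if bound is not None else self.bound)

    # -- algebra (independent errors, first order) -------------------------
    def __add__(self, other) -> "UncertainValue":
        o = uv(other)
        return UncertainValue(self.value + o.value, math.hypot(self.sd, o.sd),
                              bound=self.bound or o.bound)

    __radd__ = __add__

    def __sub__(self, other) -> "UncertainValue":
        o = uv(other)
        return UncertainValue(self.value - o.value, math.hypot(self.sd, o.sd),
                              bound=self.bound)

    def __rsub__(self, other) -> "UncertainValue":
        return uv(other) - self

    def __mul__(self, other) -> "UncertainValue":
        o = uv(other)
        val = self.value * o.value
        # d(ab) = b*da (+) a*db; exact also when either central value is 0
        sd = math.hypot(o.value * self.sd, self.value * o.sd)
        return UncertainValue(val, sd, bound=self.bound or o.bound)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "UncertainValue":
        o = uv(other)
        if o.value == 0:
            raise ZeroDivisionError("division by an UncertainValue with zero central value")
        val = self.value / o.value
        if self.value == 0:
            # relative propagation is undefined at 0; scale the absolute sd
            sd = self.sd / abs(o.value)
        else:
            sd = abs(val) * math.hypot(self.rel_sd, o.rel_sd)
        bound = self.bound
        if o.bound is not None:
            # dividing by an upper bound yields a lower bound and vice versa
            flipped = {"upper": "lower", "lower": "upper"}[o.bound]
            bound = bound or flipped
        return UncertainValue(val, sd, bound=bound, note=self.note or o.note)

    def __rtruediv__(self, other) -> "UncertainValue":
        return uv(other) / self

    def __neg__(self) -> "UncertainValue":
        return UncertainValue(-self.value, self.sd, bound=self.bound, note=self.note)

    def __float__(self) -> float:
        return float(self.value)

    def __str__(self) -> str:
        prefix = {"upper": "< ", "lower": "> ", None: ""}[self.bound]
        return f"{prefix}{self.value:.3g} +/- {self.sd:.2g}"


def uv(x) -> UncertainValue:
    """Coerce a number into an exact (zero-sd) :class:`UncertainValue`."""
    if isinstance(x, UncertainValue):
        return x
    return UncertainValue(float(x), 0.0)


def uv_ratio(a, b) -> UncertainValue:
    """``a / b`` with first-order propagation (independent errors)."""
    return uv(a) / uv(b)


def uv_product(a, b) -> UncertainValue:
    """``a * b`` with first-order propagation (independent errors)."""
    return uv(a) * uv(b)


def uv_sum(a, b) -> UncertainValue:
    """``a + b`` with quadrature-combined standard deviations."""
    return uv(a) + uv(b)


def uv_scale(a, k: float) -> UncertainValue:
    """Scale value and sd by a constant ``k`` (sd by ``|k|``)."""
    a = uv(a)
    return UncertainValue(a.value * k, a.sd * abs(k), bound=a.bound, note=a.note)
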