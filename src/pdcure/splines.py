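"""Restricted cubic spline bases on the log-time axis.

Two variants are provided:

* the standard restricted (natural) cubic spline of Durrleman and
  Simon: a linear term plus truncated-cubic terms constrained to be
  linear beyond the boundary knots; and
* a cure-constrained basis built from *reversed* log time relative to
  the last knot, whose every basis function has exactly zero value and
  zero derivative at and beyond the last knot.  Any linear combination
  is therefore constant there, which is what forces an exact survival
  plateau in the flexible cure model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplineBasisSpec", "rcs_basis", "cure_basis", "default_knots"]


@dataclass(frozen=True)
class SplineBasisSpec:
    """Knot positions (log-time axis) and the plateau constraint flag."""

    knots: tuple[float, ...]
    cure_constraint: bool = False

    def __post_init__(self) -> None:
        if len(self.knots) < 2:
            raise ValueError("at least 2 knots required")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if self.cure_constraint and len(self.knots) < 3:
            raise ValueError("cure constraint needs at least 3 knots")

    @property
    def n_basis(self) -> int:
        """Free basis functions (excluding the intercept)."""
        k = len(self.knots)
        return k - 2 if self.cure_constraint else k - 1


def _rcs_terms(u: np.ndarray, knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Durrleman-Simon basis: [u, nonlinear terms] with derivatives.

    Nonlinear term j (one per interior knot k_j):
        [(u-k_j)+^3 - l_j (u-k_1)+^3 - (1-l_j)(u-k_K)+^3] / (k_K-k_1)^2
    with l_j = (k_K - k_j)/(k_K - k_1); zero below the first knot and
    linear beyond the last.
    """
    k1, kK = knots[0], knots[-1]
    span2 = (kK - k1) ** 2
    vals = [u]
    ders = [np.ones_like(u)]
    for kj in knots[1:-1]:
        lam = (kK - kj) / (kK - k1)
        p_j = np.clip(u - kj, 0.0, None)
        p_1 = np.clip(u - k1, 0.0, None)
        p_K = np.clip(u - kK, 0.0, None)
        vals.append((p_j**3 - lam * p_1**3 - (1 - lam) * p_K**3) / span2)
        ders.append(3.0 * (p_j**2 - lam * p_1**2 - (1 - lam) * p_K**2) / span2)
    return np.stack(vals, axis=-1), np.stack(ders, axis=-1)


def rcs_basis(u, spec: SplineBasisSpec) -> tuple[np.ndarray, np.ndarray]:
    """Unconstrained restricted cubic spline basis values and derivatives.

    Returns arrays of shape (..., n_basis): the linear term followed by
    one nonlinear term per interior knot.  With 2 knots only the linear
    term remains.
    """
    u = np.asarray(u, dtype=float)
    return _rcs_terms(u, np.asarray(spec.knots, dtype=float))


def cure_basis(u, spec: SplineBasisSpec) -> tuple[np.ndarray, np.ndarray]:
    """Plateau-constrained basis values and derivatives.

    Computed from reversed log time r = k_last - u with reversed knot
    positions; only the nonlinear reversed terms are kept, so every
    basis function is identically zero (value and derivative) for
    u >= k_last, and tends to a linear function of u for u below the
    first knot.
    """
    if not spec.cure_constraint:
        raise ValueError("spec does not carry the cure constraint")
    u = np.asarray(u, dtype=float)
    knots = np.asarray(spec.knots, dtype=float)
    r = knots[-1] - u
    rknots = np.sort(knots[-1] - knots)
    vals, ders = _rcs_terms(r, rknots)
    # drop the linear reversed term; d/du = -d/dr for the rest
    return vals[..., 1:], -ders[..., 1:]


def default_knots(event_times: np.ndarray, n_interior: int = 2,
                  cure_constraint: bool = True,
                  boundary_offset: float = 0.01) -> SplineBasisSpec:
    """Knots from uncensored times: boundaries at the extreme log event
    times, interior knots at event-time centiles on the log scale.

    With the cure constraint the spline slope is exactly zero at the
    last knot, so an event exactly there would have zero hazard and an
    unbounded likelihood contribution; the upper boundary knot is
    therefore shifted ``boundary_offset`` log-time units past the
    largest event time, placing the plateau just beyond the last
    observed failure.
    """
    t = np.asarray(event_times, dtype=float)
    t = t[t > 0]
    if len(np.unique(t)) < n_interior + 2:
        raise ValueError("too few distinct event times for the requested knots")
    u = np.log(t)
    hi = u.max() + (boundary_offset if cure_constraint else 0.0)
    if cure_constraint:
        # Late interior knots: the plateau transition lives in the upper
        # tail of the event-time distribution, and evenly spaced centiles
        # starve it of flexibility (they also fit demonstrably worse).
        qs = (np.array([0.90, 0.98]) if n_interior == 2
              else np.linspace(0.5, 0.98, n_interior + 2)[1:-1])
        qs = np.concatenate([[0.0], qs, [1.0]])
    else:
        qs = np.linspace(0.0, 1.0, n_interior + 2)
    knots = np.quantile(u, qs)
    knots[0], knots[-1] = u.min(), hi
    if np.any(np.diff(knots) <= 0):
        # fall back to evenly spaced knots when centiles collide
        knots = np.linspace(u.min(), hi, n_interior + 2)
    return SplineBasisSpec(knots=tuple(knots), cure_constraint=cure_constraint)
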