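"""Closed-form dose-response models for inducible expression systems.

Two forward models are provided:

* a four-parameter logistic (4PL) for univariate inducer titrations, in the
  parameterization ``y = y0 + (ymax - y0) / (1 + (ec50/x)**n)``, which is
  defined (by continuity) at zero inducer and evaluates there to the basal
  level ``y0`` exactly; and
* a two-input AND-gate surface built from Hill occupancies with a leak
  fraction ``f1``: the fraction of maximal expression reachable with the
  first inducer alone. ``1/f1`` is the dual-induction enhancement.

Derived quantities (EC quantiles, the EC90/EC10 dynamic-range ratio DRLR)
have closed forms and are exposed here so the fitting layer can report them
without numeric root finding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParameterError",
    "FourPLParams",
    "ANDGateParams",
    "hill",
    "eval_four_pl",
    "eval_and_gate",
    "ec_quantile",
    "drlr_analytic",
]


class ParameterError(ValueError):
    """A model parameter is outside its admissible domain."""


@dataclass(frozen=True)
class FourPLParams:
    """Four-parameter logistic curve parameters.

    Attributes
    ----------
    y0 : float
        Basal response at zero inducer (RFU/OD, >= 0).
    ymax : float
        Saturating response (RFU/OD); must exceed ``y0`` for an
        activating curve.
    ec50 : float
        Half-maximal inducer concentration (uM, > 0).
    n : float
        Hill coefficient (dimensionless, > 0).
    """

    y0: float
    ymax: float
    ec50: float
    n: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.y0, self.ymax, self.ec50, self.n]).all():
            raise ParameterError("4PL parameters must be finite")
        if self.ec50 <= 0:
            raise ParameterError(f"ec50 must be positive, got {self.ec50}")
        if self.n <= 0:
            raise ParameterError(f"Hill coefficient n must be positive, got {self.n}")
        if self.y0 < 0:
            raise ParameterError(f"basal y0 must be >= 0, got {self.y0}")


@dataclass(frozen=True)
class ANDGateParams:
    """Parameters of the leaky two-input AND-gate expression model.

    The response to inducers I and P is

    ``y(I, P) = y0 + dy * H(I; k1, n) * (f1 + (1 - f1) * H(P; k2, n2))``

    with ``H(x; K, n) = x^n / (K^n + x^n)`` the Hill occupancy. The shared
    Hill coefficient ``n`` applies to both axes unless a per-inducer ``n2``
    is given. ``f1`` is the fraction of expression independent of P:
    ``f1 = 1`` makes the gate P-independent, ``f1 = 0`` a strict AND gate.
    """

    y0: float
    dy: float
    n: float
    k1: float
    k2: float
    f1: float
    n2: float | None = None

    def __post_init__(self) -> None:
        vals = [self.y0, self.dy, self.n, self.k1, self.k2, self.f1]
        if self.n2 is not None:
            vals.append(self.n2)
        if not np.isfinite(vals).all():
            raise ParameterError("AND-gate parameters must be finite")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ParameterError("half-maximal constants k1, k2 must be positive")
        if self.n <= 0 or (self.n2 is not None and self.n2 <= 0):
            raise ParameterError("Hill coefficients must be positive")
        if not 0.0 <= self.f1 <= 1.0:
            raise ParameterError(f"leak fraction f1 must lie in [0, 1], got {self.f1}")
        if self.dy < 0 or self.y0 < 0:
            raise ParameterError("y0 and dy must be >= 0")

    @property
    def enhancement(self) -> float:
        """Dual-induction enhancement 1/f1 (inf for a strict AND gate)."""
        return np.inf if self.f1 == 0 else 1.0 / self.f1


def hill(x, k: float, n: float):
    """Hill occupancy ``x^n / (k^n + x^n)``, defined as 0 at x = 0.

    Vectorized over ``x``; computed via ``1 / (1 + (k/x)^n)`` which is
    numerically stable for large ``x`` and large ``n``.
    """
    if k <= 0 or n <= 0:
        raise ParameterError("hill requires k > 0 and n > 0")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentrations must be >= 0")
    out = np.zeros_like(x)
    pos = x > 0
    with np.errstate(over="ignore"):
        out[pos] = 1.0 / (1.0 + (k / x[pos]) ** n)
    return out if out.ndim else float(out)


def eval_four_pl(x, params: FourPLParams):
    """Evaluate the four-parameter logistic at concentration(s) ``x`` (uM)."""
    return params.y0 + (params.ymax - params.y0) * hill(x, params.ec50, params.n)


def eval_and_gate(i, p, params: ANDGateParams):
    """Evaluate the AND-gate surface at inducer concentrations (uM).

    Broadcasts ``i`` against ``p``; pass a column and a row vector to get
    the full bivariate response matrix.
    """
    n2 = params.n if params.n2 is None else params.n2
    hi = hill(i, params.k1, params.n)
    hp = hill(p, params.k2, n2)
    return params.y0 + params.dy * hi * (params.f1 + (1.0 - params.f1) * hp)


def ec_quantile(params: FourPLParams, q: float) -> float:
    """Concentration at which the normalized response reaches fraction ``q``.

    Solves ``(y - y0)/(ymax - y0) = q`` for the 4PL, giving
    ``ec50 * (q/(1-q))**(1/n)``. ``q = 0.5`` returns the EC50.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile q must lie strictly in (0, 1), got {q}")
    return params.ec50 * (q / (1.0 - q)) ** (1.0 / params.n)


def drlr_analytic(params: FourPLParams) -> float:
    """Dynamic range of ligand response, DRLR = EC90/EC10 = 81**(1/n).

    Depends only on the Hill coefficient: small values indicate a digital
    (switch-like) response, large values an analogue (tuneable) one.
    """
    return 81.0 ** (1.0 / params.n)
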