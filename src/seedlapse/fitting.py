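"""Growth-curve regression, model selection by R², and rate curves.

Five candidate families are supported: exponential ``a·e^(bx)``, linear
``ax + b``, logarithmic ``a·ln(x) + b``, power ``a·x^b`` and polynomials of
a configurable order.  Exponential and power families are fitted by
log-linearization (deterministic, no iterative optimizer); R² is always
scored on the original y scale.

Two R² conventions are carried on every fit: the explained-over-total form
``Σ(ŷ−ȳ)²/Σ(y−ȳ)²`` (the primary score) and the familiar residual form
``1 − Σ(y−ŷ)²/Σ(y−ȳ)²`` (diagnostic).  For a linear-in-parameters least
squares fit with intercept the two coincide; for log-linearized fits the
explained form can exceed 1, which is why both are kept.

The germination-potential curve is the first derivative of the winning
polynomial, with its maximum located exactly on a closed time domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from seedlapse.morphometry import GrowthSeries

FAMILIES = ("exponential", "linear", "logarithmic", "power", "polynomial")

#: R² differences below this are treated as ties, broken toward fewer parameters.
TIE_EPS = 1e-12


@dataclass(frozen=True)
class PolyCoeffs:
    """Polynomial coefficients in descending degree order (c_k ... c_0)."""

    coeffs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.coeffs) == 0:
            raise ValueError("a polynomial needs at least one coefficient")
        if len(self.coeffs) > 1 and self.coeffs[0] == 0:
            raise ValueError("leading coefficient must be nonzero (trim the degree instead)")

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1

    def __call__(self, x):
        return evaluate_poly(self, x)


def evaluate_poly(p: PolyCoeffs, x):
    """Horner-scheme evaluation; accepts scalars or arrays."""
    acc = np.zeros_like(np.asarray(x, dtype=float)) if np.ndim(x) else 0.0
    for c in p.coeffs:
        acc = acc * x + c
    return acc


def differentiate(p: PolyCoeffs) -> PolyCoeffs:
    """Power-rule first derivative; degree k -> max(k-1, 0)."""
    k = p.degree
    if k == 0:
        return PolyCoeffs((0.0,))
    derived = tuple(c * (k - i) for i, c in enumerate(p.coeffs[:-1]))
    # Trim any leading zeros produced by zero coefficients.
    first = next((i for i, c in enumerate(derived) if c != 0), len(derived) - 1)
    return PolyCoeffs(derived[first:])


def r_squared(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Explained-over-total coefficient of determination Σ(ŷ−ȳ)²/Σ(y−ȳ)²."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y and yhat must share a length of at least 2")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("R² is undefined for constant observations")
    return float(np.sum((yhat - y.mean()) ** 2) / sst)


def r_squared_residual(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Residual-form coefficient of determination 1 − Σ(y−ŷ)²/Σ(y−ȳ)²."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y and yhat must share a length of at least 2")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("R² is undefined for constant observations")
    return 1.0 - float(np.sum((y - yhat) ** 2) / sst)


@dataclass(frozen=True)
class FitResult:
    """One fitted family with both R² forms and the fitted values."""

    family: str
    params: tuple[float, ...]
    r2: float
    r2_residual: float
    x: tuple[float, ...]
    y: tuple[float, ...]
    yhat: tuple[float, ...]
    order: int | None = None  # polynomial order, when applicable

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def poly(self) -> PolyCoeffs:
        if self.family != "polynomial":
            raise ValueError(f"{self.family} fit has no polynomial coefficients")
        return PolyCoeffs(self.params)

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        a = self.params
        if self.family == "polynomial":
            return evaluate_poly(PolyCoeffs(self.params), x)
        if self.family == "linear":
            return a[0] * x + a[1]
        if self.family == "exponential":
            return a[0] * np.exp(a[1] * x)
        if self.family == "logarithmic":
            return a[0] * np.log(x) + a[1]
        if self.family == "power":
            return a[0] * np.power(x, a[1])
        raise ValueError(f"unknown family {self.family!r}")

    def derivative_at(self, x: float) -> float:
        """Slope of the fitted curve at x (used by the monotone-trend check)."""
        a = self.params
        if self.family == "polynomial":
            return float(evaluate_poly(differentiate(PolyCoeffs(self.params)), x))
        if self.family == "linear":
            return float(a[0])
        if self.family == "exponential":
            return float(a[0] * a[1] * math.exp(a[1] * x))
        if self.family == "logarithmic":
            return float(a[0] / x)
        if self.family == "power":
            return float(a[0] * a[1] * x ** (a[1] - 1.0))
        raise ValueError(f"unknown family {self.family!r}")

    def expression(self, decimals: int = 4) -> str:
        """Human-readable equation with coefficients rounded for reports."""
        a = [round(p, decimals) for p in self.params]
        if self.family == "linear":
            return f"{a[0]}x + {a[1]}"
        if self.family == "exponential":
            return f"{a[0]}e^({a[1]}x)"
        if self.family == "logarithmic":
            return f"{a[0]}ln(x) + {a[1]}"
        if self.family == "power":
            return f"{a[0]}x^{a[1]}"
        terms = []
        k = len(a) - 1
        for i, c in enumerate(a):
            power = k - i
            if power == 0:
                terms.append(f"{c}")
            elif power == 1:
                terms.append(f"{c}x")
            else:
                terms.append(f"{c}x^{power}")
        return " + ".join(terms)


def _make_result(family: str, params, x, y, yhat, order=None) -> FitResult:
    return FitResult(
        family=family,
        params=tuple(float(p) for p in params),
        r2=r_squared(y, yhat),
        r2_residual=r_squared_residual(y, yhat),
        x=tuple(float(v) for v in x),
        y=tuple(float(v) for v in y),
        yhat=tuple(float(v) for v in yhat),
        order=order,
    )


def fit_family(series: GrowthSeries, family: str, order: int = 3) -> FitResult:
    """Fit one candidate family to a growth series by least squares.

    Linear and polynomial families use ordinary least squares on the raw
    design; logarithmic regresses y on ln x; exponential and power are
    log-linearized (ln y on x, resp. ln y on ln x), which requires y > 0.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    x = series.x
    y = series.y
    n = len(x)

    if family == "polynomial":
        if order < 1:
            raise ValueError("polynomial order must be >= 1")
        if n < order + 1:
            raise ValueError(f"need at least {order + 1} points for an order-{order} polynomial, got {n}")
        coeffs = np.polyfit(x, y, order)
        yhat = np.polyval(coeffs, x)
        return _make_result("polynomial", coeffs, x, y, yhat, order=order)

    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")

    if family == "linear":
        a, b = np.polyfit(x, y, 1)
        return _make_result("linear", (a, b), x, y, a * x + b)

    if family == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic family requires all x > 0")
        a, b = np.polyfit(np.log(x), y, 1)
        return _make_result("logarithmic", (a, b), x, y, a * np.log(x) + b)

    if np.any(y <= 0):
        raise ValueError(f"{family} family requires all y > 0 for log-linearization")
    if family == "exponential":
        b, ln_a = np.polyfit(x, np.log(y), 1)
        a = math.exp(ln_a)
        return _make_result("exponential", (a, b), x, y, a * np.exp(b * x))
    # power
    if np.any(x <= 0):
        raise ValueError("power family requires all x > 0")
    b, ln_a = np.polyfit(np.log(x), np.log(y), 1)
    a = math.exp(ln_a)
    return _make_result("power", (a, b), x, y, a * np.power(x, b))


def select_best(
    series: GrowthSeries,
    candidates: Sequence[str | tuple[str, int]] = FAMILIES,
    monotone_check: bool = True,
    order: int = 3,
) -> FitResult:
    """Fit every candidate and return the highest-R² survivor.

    When ``monotone_check`` is on, a candidate whose fitted curve is falling
    at the right edge of the domain (negative derivative at max(x)) is
    disqualified before scoring — growth series are expected to keep rising,
    so a fitted downturn signals over-flexible models.  Ties within
    ``TIE_EPS`` go to the family with fewer parameters.
    """
    t_max = float(series.x[-1])
    results: list[FitResult] = []
    reasons: dict[str, str] = {}
    for cand in candidates:
        fam, k = (cand, order) if isinstance(cand, str) else cand
        name = fam if fam != "polynomial" else f"polynomial(order={k})"
        try:
            fit = fit_family(series, fam, order=k)
        except ValueError as exc:
            reasons[name] = f"unfittable: {exc}"
            continue
        if monotone_check and fit.derivative_at(t_max) < 0:
            reasons[name] = f"disqualified: fitted curve decreasing at x={t_max}"
            continue
        results.append(fit)
    if not results:
        detail = "; ".join(f"{k}: {v}" for k, v in reasons.items())
        raise ValueError(f"no candidate family survived selection ({detail})")
    best = results[0]
    for fit in results[1:]:
        if fit.r2 > best.r2 + TIE_EPS:
            best = fit
        elif abs(fit.r2 - best.r2) <= TIE_EPS and fit.n_params < best.n_params:
            best = fit
    return best


@dataclass(frozen=True)
class PotentialCurve:
    """First-derivative (rate) curve of a fitted growth polynomial."""

    derivative: PolyCoeffs
    domain: tuple[float, float]
    peak: tuple[float, float]  # (t*, value): exact maximum on the closed domain
    grid_peak: tuple[float, float]  # argmax on the hourly sampling grid

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError(f"degenerate domain {self.domain}")


def _poly_max_on_interval(p: PolyCoeffs, lo: float, hi: float) -> tuple[float, float]:
    """Exact maximum of a polynomial on [lo, hi]: endpoints + critical points."""
    candidates = [lo, hi]
    if p.degree >= 1:
        dp = differentiate(p)
        if dp.degree >= 1 or dp.coeffs[0] != 0:
            roots = np.roots(dp.coeffs)
            for r in roots:
                if abs(r.imag) < 1e-9 and lo <= r.real <= hi:
                    candidates.append(float(r.real))
    values = [float(evaluate_poly(p, t)) for t in candidates]
    i = int(np.argmax(values))
    return candidates[i], values[i]


def potential_curve(
    fit: FitResult,
    domain: tuple[float, float],
    grid_step: float = 1.0,
) -> PotentialCurve:
    """Differentiate a polynomial fit and locate the rate maximum.

    ``peak`` is exact (vertex/critical-point analysis on the closed domain);
    ``grid_peak`` is the argmax over the ``grid_step``-hour sampling grid,
    matching how rate peaks are read off plotted hourly curves.
    """
    lo, hi = domain
    if not lo < hi:
        raise ValueError(f"degenerate domain {domain}")
    p = fit.poly
    if p.degree < 2:
        raise ValueError(f"potential curve needs a polynomial of degree >= 2, got {p.degree}")
    dp = differentiate(p)
    peak = _poly_max_on_interval(dp, lo, hi)

    grid = np.arange(math.ceil(lo - 1e-9), math.floor(hi + 1e-9) + 1, grid_step, dtype=float)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size == 0:
        grid = np.array([lo, hi])
    vals = evaluate_poly(dp, grid)
    gi = int(np.argmax(vals))
    return PotentialCurve(derivative=dp, domain=(float(lo), float(hi)), peak=peak, grid_peak=(float(grid[gi]), float(vals[gi])))
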