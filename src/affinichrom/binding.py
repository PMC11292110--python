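"""Injection-amount-dependent binding model.

Under column overload the retention of a ligand on an immobilized
receptor decreases as the injected amount n_b grows, because the fixed
pool of binding sites n_a saturates. For a single class of homogeneous,
fast-equilibrating sites the capacity factor k' obeys the linearization

    k' n_b / (1 + k')  =  n_a  -  (k' V_m) / K_A

so plotting y = k' n_b / (1 + k') against x = k' V_m gives a straight
line with slope -1/K_A and intercept n_a. A series of injections at
increasing concentration therefore yields the association constant K_A
(L/mol) and the total amount of accessible binding sites n_a (mol) from
one ordinary least-squares fit — no column saturation run is needed,
which is the method's advantage over frontal analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .column import ColumnSystem
from .errors import (
    InsufficientDataError,
    ParameterExtractionError,
    ValidationError,
)

__all__ = [
    "Injection",
    "InjectionSeries",
    "BindingPoint",
    "BindingFit",
    "injected_moles",
    "transform_point",
    "fit_binding_line",
    "derive_parameters",
    "analyze_series",
    "rank_ligands",
]

MIN_POINTS = 3


def injected_moles(concentration: float, injection_volume: float) -> float:
    """Moles loaded per injection, n_b = c * V_inj.

    ``concentration`` in mol/L, ``injection_volume`` in litres.
    """
    if concentration <= 0:
        raise ValidationError(f"concentration must be positive, got {concentration}")
    if injection_volume <= 0:
        raise ValidationError(
            f"injection volume must be positive, got {injection_volume}"
        )
    return concentration * injection_volume


@dataclass
class Injection:
    """One chromatographic injection of a ligand.

    ``concentration`` in mol/L, ``volume`` in litres; ``t_r`` (minutes)
    and ``k`` (capacity factor) are filled in as they are measured.
    """

    concentration: float
    volume: float
    t_r: float | None = None
    k: float | None = None

    def __post_init__(self):
        if self.concentration <= 0 or self.volume <= 0:
            raise ValidationError("concentration and volume must be positive")

    @property
    def n_b(self) -> float:
        return injected_moles(self.concentration, self.volume)


@dataclass
class InjectionSeries:
    """An ordered concentration series for one analyte on one column."""

    analyte: str
    column: ColumnSystem
    injections: list[Injection]

    def __post_init__(self):
        if not self.injections:
            raise ValidationError("series must contain at least one injection")
        vols = {inj.volume for inj in self.injections}
        if len(vols) != 1:
            raise ValidationError("all injections in a series share one volume")
        concs = [inj.concentration for inj in self.injections]
        if len(set(concs)) != len(concs):
            raise ValidationError("concentrations must be pairwise distinct")


@dataclass(frozen=True)
class BindingPoint:
    """One observation in the linearized coordinates.

    x = k' V_m (litres), y = k' n_b / (1 + k') (moles).
    """

    x: float
    y: float


@dataclass
class BindingFit:
    """Result of the linearized overload fit.

    ``K_A`` = -1/slope (L/mol) and ``n_a`` = intercept (mol) are unset
    (None) when the slope is non-negative, i.e. no saturable binding was
    detected. ``se_K_A`` is a first-order (delta-method) propagation of
    the slope standard error. ``r`` is Pearson's correlation coefficient
    of the transformed points; ``r2`` its square.
    """

    slope: float
    intercept: float
    r: float
    se_slope: float
    se_intercept: float
    n_points: int
    K_A: float | None = None
    n_a: float | None = None
    se_K_A: float | None = None
    points: list[BindingPoint] = field(default_factory=list)
    residuals: np.ndarray | None = None
    monotonicity_violated: bool = False

    @property
    def r2(self) -> float:
        return self.r * self.r


def transform_point(k: float, n_b: float, v_m: float) -> BindingPoint:
    """Map a (k', n_b) observation to the linearized coordinates.

    Raises ValidationError for k' <= 0 (unretained point: excluded).
    As k' grows, y tends to n_b — heavily retained injections deposit
    essentially all loaded moles on the sites.
    """
    if k <= 0:
        raise ValidationError(
            f"capacity factor must be positive for the binding transform, got {k}"
        )
    if n_b <= 0 or v_m <= 0:
        raise ValidationError("n_b and V_m must be positive")
    return BindingPoint(x=k * v_m, y=k * n_b / (1.0 + k))


def derive_parameters(slope: float, intercept: float) -> tuple[float, float]:
    """Binding parameters from the fitted line: K_A = -1/slope, n_a = intercept.

    Raises ParameterExtractionError naming the offending quantity when
    the slope is non-negative or the intercept non-positive.
    """
    if slope >= 0:
        raise ParameterExtractionError(
            f"slope must be negative for saturable binding, got {slope}"
        )
    if intercept <= 0:
        raise ParameterExtractionError(
            f"intercept (n_a) must be positive, got {intercept}"
        )
    return -1.0 / slope, intercept


def fit_binding_line(points: list[BindingPoint]) -> BindingFit:
    """Unweighted OLS of y on x over the transformed points.

    Needs at least three points with non-degenerate x. A non-negative
    slope is not an error: the fit is returned with K_A/n_a unset so QC
    can report "no saturable binding detected".
    """
    if len(points) < MIN_POINTS:
        raise InsufficientDataError(
            f"insufficient data: {len(points)} points, need >= {MIN_POINTS}"
        )
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    if np.ptp(x) == 0:
        raise InsufficientDataError("x values are all equal; cannot fit a line")
    res = stats.linregress(x, y)
    fit = BindingFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        se_slope=float(res.stderr),
        se_intercept=float(res.intercept_stderr),
        n_points=len(points),
        points=list(points),
        residuals=y - (res.slope * x + res.intercept),
    )
    if fit.slope < 0 and fit.intercept > 0:
        fit.K_A, fit.n_a = derive_parameters(fit.slope, fit.intercept)
        # delta method: var(-1/m) ~ se_m^2 / m^4
        fit.se_K_A = fit.se_slope / fit.slope**2
    return fit


def analyze_series(series: InjectionSeries) -> BindingFit:
    """Full analysis of a concentration series: transform, fit, extract.

    Injections without a measured capacity factor, or with k' <= 0, are
    excluded. The fit carries a monotonicity flag: the overload model
    requires k' to be nonincreasing in n_b, and a series violating that
    (retention growing with load) is flagged rather than rejected.
    """
    usable = [inj for inj in series.injections if inj.k is not None and inj.k > 0]
    if len(usable) < MIN_POINTS:
        raise InsufficientDataError(
            f"insufficient data: {len(usable)} usable injections, "
            f"need >= {MIN_POINTS}"
        )
    v_m = series.column.void_volume
    ordered = sorted(usable, key=lambda inj: inj.n_b)
    ks = np.array([inj.k for inj in ordered])
    violated = bool(np.any(np.diff(ks) > 0))
    points = [transform_point(inj.k, inj.n_b, v_m) for inj in ordered]
    fit = fit_binding_line(points)
    fit.monotonicity_violated = violated
    return fit


def rank_ligands(fits: dict[str, BindingFit]) -> list[tuple[str, float]]:
    """Rank analytes by association constant, strongest binder first.

    Fits without a valid K_A are dropped; ties break alphabetically by
    analyte label. Returns (label, K_A) pairs.
    """
    valid = [(name, f.K_A) for name, f in fits.items() if f.K_A is not None]
    if not valid:
        raise InsufficientDataError("no fit with a valid K_A to rank")
    return sorted(valid, key=lambda item: (-item[1], item[0]))
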