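"""Sample-size determination by inverting a monotone smoothed power curve.

Power is estimated on a grid of control-arm sizes ``n = nL + k*w`` for
``k = 0..B`` with ``w = round((nU - nL)/B)``, each grid point using an
independent seed derived from the root seed and n.  Because Monte-Carlo noise
can locally invert the grid powers, a monotone nondecreasing curve is fitted:
isotonic regression (pool-adjacent-violators) at the grid points, joined by a
shape-preserving monotone cubic (PCHIP) interpolant.  The required sample
size is the smallest integer in [nL, nU] whose fitted power reaches the
desired power ``epwr``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

from .config import ScenarioConfig
from .power import PowerResult, calculate_power, resolve_scenario

__all__ = [
    "SizeSearchSpec",
    "GridPoint",
    "PowerCurve",
    "SizeResult",
    "power_grid",
    "fit_monotone_curve",
    "calculate_size",
]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SizeSearchSpec:
    """Bounds and resolution of the sample-size search."""

    nL: int
    nU: int
    epwr: float
    B: int = 10

    def __post_init__(self) -> None:
        if self.nL < 2 or self.nU <= self.nL:
            raise ValueError("need 2 <= nL < nU")
        if self.B < 2:
            raise ValueError("B must be >= 2")
        if not 0 < self.epwr < 1:
            raise ValueError("epwr must lie in (0, 1)")
        if self.w < 1:
            raise ValueError("grid step round((nU - nL)/B) must be >= 1")

    @property
    def w(self) -> int:
        return _round_half_away((self.nU - self.nL) / self.B)

    @property
    def grid(self) -> np.ndarray:
        ns = self.nL + self.w * np.arange(self.B + 1)
        return np.unique(ns)


@dataclass(frozen=True)
class GridPoint:
    n: int
    power: float
    mc_se: float


@dataclass(frozen=True)
class PowerCurve:
    """A fitted nondecreasing power curve on [grid min, grid max]."""

    grid_n: np.ndarray
    grid_power: np.ndarray
    fitted_power: np.ndarray  # isotonic values at the grid

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_interp", PchipInterpolator(self.grid_n, self.fitted_power)
        )

    def __call__(self, n) -> np.ndarray:
        n = np.clip(np.asarray(n, dtype=float), self.grid_n[0], self.grid_n[-1])
        return np.clip(self._interp(n), 0.0, 1.0)


@dataclass(frozen=True)
class SizeResult:
    """Outcome of the sample-size search."""

    n_required: int
    n_experimental: int
    grid: tuple[GridPoint, ...]
    curve: PowerCurve
    spec: SizeSearchSpec
    at_lower_bound: bool = False

    def to_dict(self) -> dict:
        return {
            "n_required": self.n_required,
            "n_experimental": self.n_experimental,
            "epwr": self.spec.epwr,
            "at_lower_bound": self.at_lower_bound,
            "grid": [
                {"n": p.n, "power": p.power, "mc_se": p.mc_se} for p in self.grid
            ],
        }


def _grid_seed(root_seed: int, n: int) -> int:
    """A reproducible per-grid-point seed derived from the root seed and n."""
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(int(n),))
    return int(ss.generate_state(1)[0] % (2**31))


def power_grid(config: ScenarioConfig, spec: SizeSearchSpec) -> list[GridPoint]:
    """Monte-Carlo power at each grid sample size (scenario calibrated once)."""
    resolved = resolve_scenario(config)
    points = []
    for n in spec.grid:
        result: PowerResult = calculate_power(
            resolved=resolved, n=int(n), seed=_grid_seed(config.seed, int(n))
        )
        points.append(GridPoint(n=int(n), power=result.power, mc_se=result.mc_se))
    return points


def fit_monotone_curve(points: Sequence[GridPoint | tuple]) -> PowerCurve:
    """Fit a nondecreasing, continuous power curve through grid powers.

    Isotonic regression resolves noise-induced inversions (already-monotone
    points are interpolated exactly); PCHIP joins the isotonic values without
    overshooting, so the curve stays monotone and within [0, 1].
    """
    ns = np.array([p.n if isinstance(p, GridPoint) else p[0] for p in points], float)
    powers = np.array(
        [p.power if isinstance(p, GridPoint) else p[1] for p in points], float
    )
    order = np.argsort(ns)
    ns, powers = ns[order], powers[order]
    if np.unique(ns).size != ns.size:
        raise ValueError("grid sample sizes must be distinct")
    if ns.size < 3:
        raise ValueError("need at least 3 grid points to fit a power curve")
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
    fitted = iso.fit_transform(ns, powers)
    return PowerCurve(grid_n=ns, grid_power=powers, fitted_power=fitted)


def calculate_size(config: ScenarioConfig, spec: SizeSearchSpec) -> SizeResult:
    """Smallest integer control-arm n in [nL, nU] whose fitted power >= epwr."""
    points = power_grid(config, spec)
    curve = fit_monotone_curve(points)
    integers = np.arange(spec.nL, spec.nU + 1)
    values = curve(integers)
    reaching = integers[values >= spec.epwr]
    if reaching.size == 0:
        raise ValueError(
            f"the fitted power curve stays below epwr={spec.epwr} on "
            f"[{spec.nL}, {spec.nU}]; increase nU"
        )
    n_required = int(reaching[0])
    at_lower = n_required == spec.nL
    if at_lower:
        warnings.warn(
            f"the fitted power curve already reaches epwr={spec.epwr} at "
            f"nL={spec.nL}; decrease nL to locate the required sample size",
            stacklevel=2,
        )
    resolved = resolve_scenario(config.replace(n=n_required))
    return SizeResult(
        n_required=n_required,
        n_experimental=resolved.design.n_experimental,
        grid=tuple(points),
        curve=curve,
        spec=spec,
        at_lower_bound=at_lower,
    )
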