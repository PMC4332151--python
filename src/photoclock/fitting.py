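"""Parameter estimation against normalised diurnal timeseries.

Only small free-parameter subsets are fitted (the clock core is fixed);
the flagship use is the five target-specific parameters (basal rate, maximal
rate, half-saturation, Hill coefficient, decay) of a PIF-driven transcript.
Because target transcripts feed nothing back into the network, their
parameters can be fitted against a frozen PIF-activity trajectory — the
default fast path.  A fully general (but slow) residual that re-simulates the
whole model is also provided.

The optimiser is a seeded multi-start around bounded local least squares
(scipy ``least_squares``/TRF on log-scale parameters); results are exactly
reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import least_squares

from .environment import Environment, apply_temperature
from .genotypes import Genotype, WT
from .observables import Timeseries, normalise_to_peak
from .parameters import ParameterSet
from .registry import SPECIES_INDEX
from .simulate import last_cycle, simulate


@dataclass
class FitSpec:
    """What to fit: free parameter bounds, data, optimiser settings."""

    free: dict[str, tuple[float, float]]
    datasets: dict[str, Timeseries]
    multi_start: int = 20
    seed: int = 0
    tol: float = 1e-10
    normalise: bool = False  # compare on the data's absolute (relative-expression) scale

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.free.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
            if lo <= 0:
                raise ValueError(f"bounds must be positive (log-scale fit): {name}")

    @classmethod
    def around(cls, p: ParameterSet, names, factor: float = 10.0, **kw) -> "FitSpec":
        """Bounds ``value/factor .. value*factor`` around current values."""
        free = {nm: (p[nm] / factor, p[nm] * factor) for nm in names}
        return cls(free=free, **kw)

    def to_yaml(self, path) -> None:
        doc = {
            "free": {k: [float(a), float(b)] for k, (a, b) in self.free.items()},
            "multi_start": self.multi_start, "seed": self.seed, "tol": self.tol,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)


@dataclass
class FitResult:
    parameters: ParameterSet
    cost: float
    cost0: float
    starts: list[dict]  # per-start {x0, cost}
    success: bool


def pif_activity_trajectory(
    p: ParameterSet, env: Environment, g: Genotype = WT
) -> Timeseries:
    """Entrained last-cycle PIF activity (PIF_p attenuated by the Interactor)."""
    pt = apply_temperature(p, env.temperature)
    r = simulate(pt, env, g, days=1)
    zt, X = last_cycle(r)
    act = X[:, SPECIES_INDEX["PIF_p"]] / (
        1.0 + X[:, SPECIES_INDEX["INT_p"]] / p["k_int_pif"])
    return Timeseries(zt, act, label=f"PIF_act|{g.label}|{env.light.photoperiod.label}")


def integrate_target(
    act: Timeseries, v0: float, v: float, k: float, h: float, d: float,
    induced: bool = True,
) -> Timeseries:
    """Periodic solution of a PIF-driven target transcript over one cycle.

    m' = a(t) - d*m with a(t) = v0 + v*act^h/(k^h + act^h) (induced) or
    a(t) = v0 + v/(1 + (act/k)^h) (repressed).  The ODE is linear in m, so the
    periodic initial condition is solved exactly from one trial pass.
    """
    zt, a_in = act.zt, act.value
    if induced:
        ph = a_in ** h
        a = v0 + v * ph / (k ** h + ph)
    else:
        a = v0 + v / (1.0 + (a_in / k) ** h)
    T = zt[-1] - zt[0]
    # trapezoid-exponential pass from m0 = 0
    m = np.zeros_like(a)
    dt = np.diff(zt)
    decay = np.exp(-d * dt)
    for i in range(1, len(zt)):
        # exact step for piecewise-linear forcing
        a0, a1 = a[i - 1], a[i]
        e = decay[i - 1]
        if d > 0:
            slope = (a1 - a0) / dt[i - 1]
            m[i] = (m[i - 1] * e + (a0 / d) * (1 - e)
                    + slope * (dt[i - 1] / d - (1 - e) / d ** 2))
        else:
            m[i] = m[i - 1] + 0.5 * (a0 + a1) * dt[i - 1]
    # periodic initial condition: m*(0) = m_forced(T) / (1 - e^{-dT})
    eT = np.exp(-d * T)
    m0 = m[-1] / (1.0 - eT) if d > 0 else m[-1]
    m += m0 * np.exp(-d * (zt - zt[0]))
    return Timeseries(zt, m, label=act.label)


TARGET_PARAM_NAMES = ("v0", "v", "k", "h", "d")


def target_residual_builder(
    gene: str,
    activities: dict[str, Timeseries],
    datasets: dict[str, Timeseries],
    p: ParameterSet,
    induced: bool = True,
):
    """Residual function over the five target-specific parameters of ``gene``.

    ``activities`` maps each dataset key to the frozen PIF-activity trajectory
    of its condition; the model series is interpolated onto the data ZT grid.
    """
    if set(activities) != set(datasets):
        raise KeyError("activities and datasets must share keys")
    pref = gene.lower()

    def param_names() -> list[str]:
        if induced:
            return [f"v0_{pref}", f"v_{pref}", f"k_{pref}", f"h_{pref}", f"d_{pref}"]
        return [f"v_{pref}", f"k_{pref}", f"h_{pref}", f"d_{pref}"]

    def residual(q: ParameterSet) -> np.ndarray:
        if induced:
            args = (q[f"v0_{pref}"], q[f"v_{pref}"], q[f"k_{pref}"],
                    q[f"h_{pref}"], q[f"d_{pref}"])
        else:
            args = (0.0, q[f"v_{pref}"], q[f"k_{pref}"],
                    q[f"h_{pref}"], q[f"d_{pref}"])
        out = []
        for key in sorted(datasets):
            m = integrate_target(activities[key], *args, induced=induced)
            d = datasets[key]
            out.append(np.interp(d.zt, m.zt, m.value) - d.value)
        return np.concatenate(out)

    residual.param_names = param_names()
    return residual


def full_model_residual_builder(specs, p: ParameterSet):
    """Residual that re-simulates the full model for each dataset.

    ``specs`` is a list of (key, species, genotype, env, data) tuples.  Slow:
    intended for small problems only.
    """

    def residual(q: ParameterSet) -> np.ndarray:
        out = []
        for key, species, g, env, data in specs:
            qt = apply_temperature(q, env.temperature)
            r = simulate(qt, env, g, days=1)
            zt, X = last_cycle(r)
            mv = np.interp(data.zt, zt, X[:, SPECIES_INDEX[species]])
            out.append(mv - data.value)
        return np.concatenate(out)

    return residual


def fit(p0: ParameterSet, spec: FitSpec, residual=None) -> FitResult:
    """Seeded multi-start bounded local least squares over ``spec.free``.

    The first start is ``p0`` itself; the remaining ``multi_start - 1`` are
    log-uniform draws within bounds.  The returned cost never exceeds the cost
    at ``p0``.  With no free parameters, returns ``p0`` unchanged.
    """
    names = list(spec.free)
    if residual is None:
        raise ValueError("a residual function is required "
                         "(see target_residual_builder / full_model_residual_builder)")

    def cost_of(q: ParameterSet) -> float:
        r = residual(q)
        return float(np.dot(r, r))

    c0 = cost_of(p0)
    if not names:
        return FitResult(p0.copy(), c0, c0, [], success=True)

    lo = np.log(np.array([spec.free[n][0] for n in names]))
    hi = np.log(np.array([spec.free[n][1] for n in names]))

    def with_theta(theta: np.ndarray) -> ParameterSet:
        q = p0.copy()
        for nm, t in zip(names, theta):
            q.set(nm, float(np.exp(t)), "fitted")
        return q

    def vec_residual(theta: np.ndarray) -> np.ndarray:
        return residual(with_theta(theta))

    rng = np.random.default_rng(spec.seed)
    x0_list = [np.clip(np.log([p0[n] for n in names]), lo, hi)]
    for _ in range(max(spec.multi_start - 1, 0)):
        x0_list.append(lo + rng.random(len(names)) * (hi - lo))

    starts, best_theta, best_cost, n_fail = [], None, np.inf, 0
    for x0 in x0_list:
        try:
            sol = least_squares(vec_residual, x0, bounds=(lo, hi), method="trf",
                                xtol=spec.tol, ftol=spec.tol, gtol=spec.tol)
            c = float(2 * sol.cost)  # least_squares cost = 0.5 * sum r^2
        except Exception:  # cost failure at this start
            n_fail += 1
            starts.append({"x0": np.exp(x0), "cost": np.nan})
            continue
        starts.append({"x0": np.exp(x0), "cost": c})
        if c < best_cost:
            best_cost, best_theta = c, sol.x
    if best_theta is None:
        raise RuntimeError(
            f"optimisation failed at every one of {n_fail} start(s)")
    if best_cost <= c0:
        return FitResult(with_theta(best_theta), best_cost, c0, starts, True)
    return FitResult(p0.copy(), c0, c0, starts, True)
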