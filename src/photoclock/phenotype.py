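"""Mapping cycle-integrated transcript levels to whole-plant phenotypes.

``FT_AREA`` (area under the simulated *FT* mRNA curve over one entrained
cycle) is the molecular proxy for flowering time, and ``ATHB2_AREA`` for
hypocotyl elongation.  Simple monotone saturating maps translate the areas to
days-to-flower and hypocotyl length; these stand in for the developmental
mechanisms downstream and can be recalibrated per study (absolute phenotype
values differ between laboratories).

Default calibration anchors are representative SD/LD wild-type values shipped
in ``data/flowering_anchors_synthetic.tsv`` and
``data/hypocotyl_anchors_synthetic.tsv`` (synthetic stand-ins for published
Col-0 measurements; recalibrate with :func:`calibrate_map` for real studies).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares

from .environment import Environment, SCENARIOS
from .genotypes import Genotype, WT, genotype as get_genotype
from .observables import Timeseries, auc, from_simulation
from .parameters import ParameterSet
from .simulate import simulate


def _area(p: ParameterSet, env: Environment, g: Genotype, species: str) -> float:
    from .environment import apply_temperature

    pt = apply_temperature(p, env.temperature)
    r = simulate(pt, env, g, days=1)
    return auc(from_simulation(r, species))


def ft_area(p: ParameterSet, env: Environment, g: Genotype = WT) -> float:
    """AUC of FT mRNA over one entrained cycle (dimensionless * hours)."""
    return _area(p, env, g, "FT_m")


def athb2_area(p: ParameterSet, env: Environment, g: Genotype = WT) -> float:
    """AUC of ATHB2 mRNA over one entrained cycle."""
    return _area(p, env, g, "ATHB2_m")


@dataclass(frozen=True)
class PhenotypeMap:
    """Monotone saturating map from a transcript AUC to a phenotype.

    flowering:  days = floor + range / (1 + (A/K)^h)   (non-increasing in A)
    hypocotyl:  mm   = floor + range * A^h / (K^h + A^h)  (non-decreasing in A)
    """

    kind: str  # "flowering" | "hypocotyl"
    floor: float
    range: float
    K: float
    h: float
    calibrated: bool = False
    provenance: str = "default"

    def __post_init__(self) -> None:
        if self.kind not in ("flowering", "hypocotyl"):
            raise ValueError("kind must be 'flowering' or 'hypocotyl'")
        if self.range < 0 or self.K <= 0 or self.h <= 0:
            raise ValueError("invalid map parameters")

    @property
    def ceiling(self) -> float:
        return self.floor + self.range

    def __call__(self, area) -> np.ndarray | float:
        area = np.asarray(area, dtype=float)
        if np.any(area < 0):
            raise ValueError("area must be >= 0")
        with np.errstate(divide="ignore"):
            x = (area / self.K) ** self.h
        if self.kind == "flowering":
            y = self.floor + self.range / (1.0 + x)
        else:
            y = self.floor + self.range * x / (1.0 + x)
        y = np.clip(y, self.floor, self.ceiling)
        return float(y) if y.ndim == 0 else y

    def to_yaml(self, path) -> None:
        doc = {k: getattr(self, k) for k in
               ("kind", "floor", "range", "K", "h", "calibrated", "provenance")}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "PhenotypeMap":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def calibrate_map(
    pairs,
    kind: str = "flowering",
    floor: float | None = None,
    h: float = 2.0,
    free: tuple[str, ...] = ("range", "K"),
) -> PhenotypeMap:
    """Least-squares fit of the map family to (area, phenotype) pairs.

    With as many pairs as free parameters the fit interpolates them exactly.
    Non-monotone pairs (for the family's direction) raise a warning and are
    fitted anyway.
    """
    pairs = [(float(a), float(y)) for a, y in pairs]
    if len(pairs) < 2:
        raise ValueError("need at least 2 calibration pairs")
    areas = np.array([a for a, _ in pairs])
    ys = np.array([y for _, y in pairs])
    if len(np.unique(areas)) != len(areas):
        raise ValueError("calibration areas must be distinct")

    order = np.argsort(areas)
    dy = np.diff(ys[order])
    expected_sign = -1.0 if kind == "flowering" else 1.0
    if np.any(expected_sign * dy < 0):
        warnings.warn(
            f"calibration pairs are not monotone in the {kind} direction; "
            "fitting anyway", stacklevel=2)

    if floor is None:
        floor = float(ys.min()) * 0.9 if kind == "flowering" else 0.0

    names = list(free)
    defaults = {"range": float(np.ptp(ys)) or 1.0,
                "K": float(np.median(areas)) or 1.0, "h": h, "floor": floor}

    def build(theta):
        params = dict(defaults)
        params.update({nm: float(np.exp(t)) if nm != "floor" else float(t)
                       for nm, t in zip(names, theta)})
        return PhenotypeMap(kind=kind, calibrated=True, provenance="fitted",
                            **params)

    def resid(theta):
        return build(theta)(areas) - ys

    theta0 = [np.log(defaults[nm]) if nm != "floor" else defaults[nm]
              for nm in names]
    sol = least_squares(resid, theta0, method="lm" if len(names) == len(pairs)
                        else "trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return build(sol.x)


def days_to_flower(area: float, m: PhenotypeMap) -> float:
    if m.kind != "flowering":
        raise ValueError("map is not a flowering map")
    if not m.calibrated:
        raise ValueError("map is not calibrated")
    return float(m(area))


def hypocotyl_length(area: float, m: PhenotypeMap) -> float:
    if m.kind != "hypocotyl":
        raise ValueError("map is not a hypocotyl map")
    if not m.calibrated:
        raise ValueError("map is not calibrated")
    return float(m(area))


def _read_anchor_table(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("photoclock.data") / name
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def default_maps(p: ParameterSet) -> tuple[PhenotypeMap, PhenotypeMap]:
    """Calibrate the two default maps against the packaged SD/LD anchors.

    Simulates wild type at the anchor photoperiods, pairs the resulting areas
    with the anchor phenotypes, and fits (range, K) per family.
    """
    fl = _read_anchor_table("flowering_anchors_synthetic.tsv")
    hy = _read_anchor_table("hypocotyl_anchors_synthetic.tsv")
    fl_pairs = [(ft_area(p, Environment.make(h)), d)
                for h, d in zip(fl["photoperiod_h"], fl["days_to_flower"])]
    hy_pairs = [(athb2_area(p, Environment.make(h)), mm)
                for h, mm in zip(hy["photoperiod_h"], hy["length_mm"])]
    fmap = calibrate_map(fl_pairs, kind="flowering")
    hmap = calibrate_map(hy_pairs, kind="hypocotyl")
    return fmap, hmap


def photoperiod_scan(
    p: ParameterSet,
    g: Genotype | str = WT,
    photoperiods=tuple(range(4, 22, 2)),
    temperature: str = "reference_22C",
    maps: tuple[PhenotypeMap, PhenotypeMap] | None = None,
) -> pd.DataFrame:
    """FT/ATHB2 areas and mapped phenotypes across photoperiods.

    Returns one row per photoperiod with the entrainment flag; arrhythmic or
    extreme photoperiods (0L, 24L) produce flagged rows rather than errors.
    """
    from .environment import apply_temperature

    if isinstance(g, str):
        g = get_genotype(g)
    for h in photoperiods:
        if not 0.0 <= h <= 24.0:
            raise ValueError(f"photoperiod {h} outside [0, 24]")
    if maps is None:
        maps = default_maps(p)
    fmap, hmap = maps
    pt = apply_temperature(p, SCENARIOS[temperature])
    rows = []
    for h in photoperiods:
        env = Environment.make(h, temperature=temperature)
        r = simulate(pt, env, g, days=1)
        fa = auc(from_simulation(r, "FT_m"))
        aa = auc(from_simulation(r, "ATHB2_m"))
        rows.append({
            "photoperiod_h": h,
            "ft_area": fa,
            "athb2_area": aa,
            "days_to_flower": days_to_flower(fa, fmap),
            "hypocotyl_mm": hypocotyl_length(aa, hmap),
            "entrained": r.entrained,
        })
    return pd.DataFrame(rows)
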