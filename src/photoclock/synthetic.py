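"""Synthetic data generators standing in for the study's qPCR/microarray inputs.

Three data classes are emulated, each with a machine-readable truth record so
downstream recovery is testable end-to-end without any download:

* noisy relative-expression diurnal timeseries (qPCR-style harvest grids,
  multiplicative lognormal replicate scatter, peak-normalised);
* gene x (condition, timepoint) expression matrices with planted coherent
  clusters (model-simulated PIF-driven base profiles, antiphase and shifted
  variants, additive Gaussian noise on z-scored profiles);
* (area, phenotype) calibration pairs from a known phenotype map.

All randomness flows through an explicit seed; there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import Environment, apply_temperature
from .genotypes import Genotype, WT, genotype as get_genotype
from .clustering import ExpressionMatrix
from .observables import Timeseries, normalise_to_peak
from .parameters import ParameterSet
from .phenotype import PhenotypeMap
from .registry import SPECIES_INDEX
from .simulate import last_cycle, sample_zt, simulate

#: a typical qPCR harvest grid (dense around dawn and dusk in long days)
DEFAULT_ZT_GRID = (0, 1, 2, 4, 8, 12, 15, 16, 17, 20, 24)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal replicate noise; sigma = 0 reproduces truth."""

    sigma: float = 0.1
    seed: int = 0
    kind: str = "multiplicative-lognormal"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind != "multiplicative-lognormal":
            raise ValueError("only multiplicative-lognormal noise is supported")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            return values.copy()
        return values * rng.lognormal(mean=0.0, sigma=self.sigma, size=values.shape)


def gen_timeseries(
    p: ParameterSet,
    env: Environment,
    g: Genotype = WT,
    species=("FT_m",),
    zt_points=DEFAULT_ZT_GRID,
    noise: NoiseModel = NoiseModel(sigma=0.0),
    n_replicates: int = 1,
) -> tuple[dict[str, Timeseries], dict]:
    """Noisy, peak-normalised samples of the entrained model on a ZT grid.

    Returns ({species: Timeseries}, truth record).  Replicates are averaged
    after noising, mimicking qPCR replicate means.  The truth record carries
    the generating genotype/environment/seed and the noise-free samples.
    """
    pt = apply_temperature(p, env.temperature)
    r = simulate(pt, env, g, days=1)
    table = sample_zt(r, list(zt_points), species=list(species))
    rng = np.random.default_rng(noise.seed)
    out: dict[str, Timeseries] = {}
    truth_values = {}
    for name in species:
        clean = table.loc[name].to_numpy(dtype=float)
        reps = np.stack([noise.apply(clean, rng) for _ in range(n_replicates)])
        noisy = reps.mean(axis=0)
        ts = Timeseries(np.asarray(zt_points, dtype=float), noisy,
                        label=f"{name}|{g.label}|{env.light.photoperiod.label}")
        out[name] = normalise_to_peak(ts)
        truth_values[name] = clean
    truth = {
        "genotype": g.label,
        "hours_light": env.light.photoperiod.hours_light,
        "temperature": env.temperature.label,
        "zt_points": list(zt_points),
        "noise_sigma": noise.sigma,
        "seed": noise.seed,
        "n_replicates": n_replicates,
        "clean_values": truth_values,
    }
    return out, truth


@dataclass(frozen=True)
class ClusterSpec:
    """Planted-cluster design: fractions per cluster (rest = unstructured).

    Conditions mirror the diurnal microarray panel: two photoperiods plus
    clock/light-signalling mutants, sampled every 4 h over 2 days.
    """

    fractions: tuple[float, ...] = (0.3, 0.3, 0.2)
    conditions: tuple[tuple[str, float, str], ...] = (
        ("SD", 8.0, "WT"), ("LD", 16.0, "WT"), ("12L", 12.0, "WT"),
        ("lux", 12.0, "lux"), ("LHYox", 12.0, "LHYox"), ("phyB", 12.0, "phyB"),
    )
    n_days: int = 2
    dt: float = 4.0

    def __post_init__(self) -> None:
        if sum(self.fractions) > 1.0 + 1e-12:
            raise ValueError("cluster fractions must sum to <= 1")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("cluster fractions must be positive")


def _base_profiles(p: ParameterSet, spec: ClusterSpec) -> tuple[np.ndarray, dict]:
    """Model-derived base shapes per (cluster, condition): the in-phase
    PIF-driven target, its antiphase, and a 6-h shifted variant."""
    zt = np.arange(0.0, 24.0 * spec.n_days, spec.dt)
    blocks = []
    for _, hours, gname in spec.conditions:
        env = Environment.make(hours)
        r = simulate(p, env, get_genotype(gname), days=1)
        cyc_zt, X = last_cycle(r)
        base = X[:, SPECIES_INDEX["CLUSTER1_m"]]
        samp = np.interp(zt % 24.0, cyc_zt, base)
        z = (samp - samp.mean()) / samp.std()
        shifted = np.interp((zt + 6.0) % 24.0, cyc_zt, base)
        zs = (shifted - shifted.mean()) / shifted.std()
        blocks.append(np.stack([z, -z, zs]))
    profiles = np.concatenate(blocks, axis=1)  # (3 motifs, T*conditions)
    timepoints = {name: zt.copy() for name, _, _ in spec.conditions}
    return profiles, timepoints


def gen_cluster_matrix(
    n_genes: int,
    p: ParameterSet | None = None,
    spec: ClusterSpec = ClusterSpec(),
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray, dict]:
    """Expression matrix with planted coherent clusters + truth labels.

    Clustered genes are a cluster base profile plus i.i.d. Gaussian noise
    (sd ``noise_sd``) on the z-scored scale; unstructured genes are pure
    noise and carry truth label -1.
    """
    if len(spec.fractions) > 3:
        raise ValueError("at most 3 planted clusters are supported")
    from .parameters import default_parameters

    p = p or default_parameters()
    rng = np.random.default_rng(seed)
    profiles, timepoints = _base_profiles(p, spec)
    n_cols = profiles.shape[1]
    counts = [int(round(f * n_genes)) for f in spec.fractions]
    labels = np.full(n_genes, -1, dtype=int)
    values = np.empty((n_genes, n_cols))
    row = 0
    for cid, cnt in enumerate(counts):
        labels[row:row + cnt] = cid
        values[row:row + cnt] = (profiles[cid][None, :]
                                 + noise_sd * rng.standard_normal((cnt, n_cols)))
        row += cnt
    values[row:] = rng.standard_normal((n_genes - row, n_cols))
    genes = [f"G{i:04d}" for i in range(n_genes)]
    m = ExpressionMatrix(genes, [c for c, _, _ in spec.conditions], timepoints, values)
    truth = {
        "seed": seed, "noise_sd": noise_sd, "counts": counts,
        "n_unstructured": n_genes - row,
        # expected mean within-cluster correlation by variance decomposition:
        # corr = s2/(s2 + sd^2) with unit signal variance on the z-score scale
        "expected_within_corr": 1.0 / (1.0 + noise_sd ** 2),
    }
    return m, labels, truth


def gen_phenotype_pairs(
    true_map: PhenotypeMap,
    areas,
    noise: NoiseModel = NoiseModel(sigma=0.0),
) -> tuple[pd.DataFrame, dict]:
    """(area, phenotype) calibration pairs from a known map, plus truth."""
    areas = np.asarray(list(areas), dtype=float)
    if np.any(areas < 0):
        raise ValueError("areas must be >= 0")
    rng = np.random.default_rng(noise.seed)
    clean = np.asarray(true_map(areas), dtype=float)
    noisy = noise.apply(clean, rng)
    df = pd.DataFrame({"area": areas, "phenotype": noisy})
    truth = {"map": {k: getattr(true_map, k)
                     for k in ("kind", "floor", "range", "K", "h")},
             "clean_phenotype": clean, "sigma": noise.sigma, "seed": noise.seed}
    return df, truth
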