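"""Synthetic metabolomics matrices with DE structure, missingness and outliers.

Clean intensities follow the additive model

    x_ijk = mu_i + g_ijk + e_ijk

with a per-metabolite baseline mu_i ~ Uniform(5, 10), cell-level noise
e ~ N(0, 1), and a group effect g drawn per cell from N(m, 1) where the mean
m depends on the metabolite class and the sample's group: equally-expressed
(EE) metabolites have m = 0 in every group; up-regulated metabolites have
m = 0 in the healthy group and m = 2 in the disease group; down-regulated
metabolites are mirrored.  In the three-class design the up (down) group
means run (0, 1, 2) ((2, 1, 0)) across the groups.

Missing cells are a mix of completely-at-random cells (60% by default) and
low-abundance cells (40%) sampled from the lowest decile of each metabolite,
emulating left-censored MNAR.  Outliers replace randomly chosen observed
cells by draws from N(5·mu_i, sigma_i²), where mu_i and sigma_i² are the
mean and variance of the clean metabolite row.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np

from .core import AnnotatedMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "generate_clean",
    "inject_missing",
    "inject_outliers",
    "generate_dataset",
    "generate_benchmark_suite",
]

Design = Literal["no_class", "two_class", "three_class"]

_GROUP_NAMES = {
    "no_class": ("all",),
    "two_class": ("healthy", "disease"),
    "three_class": ("G1", "G2", "G3"),
}

# group-effect means per metabolite class, keyed by design
_EFFECT_MEANS = {
    "two_class": {"EE": (0.0, 0.0), "up": (0.0, 2.0), "down": (2.0, 0.0)},
    "three_class": {
        "EE": (0.0, 0.0, 0.0),
        "up": (0.0, 1.0, 2.0),
        "down": (2.0, 1.0, 0.0),
    },
}


@dataclass
class SimulationConfig:
    """Study-design parameters: 200 metabolites × 90 samples, 80 DE (40 up /
    40 down) vs 120 EE metabolites, equal group sizes."""

    design: Design = "two_class"
    p: int = 200
    n: int = 90
    n_de: int | None = None  # default: 40% of p (80 of 200)
    n_up: int | None = None
    n_down: int | None = None
    missing_rate: float = 0.05
    mnar_fraction: float = 0.40
    outlier_rate: float = 0.0
    seed: int = 0
    zero_noise: bool = False  # variance-0 debug mode: effects at their means

    def __post_init__(self) -> None:
        if self.design not in _GROUP_NAMES:
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "no_class":
            self.n_de = self.n_up = self.n_down = 0
        if self.n_de is None:
            self.n_de = round(0.4 * self.p)
        if self.n_up is None and self.n_down is None:
            self.n_up = self.n_de // 2
            self.n_down = self.n_de - self.n_up
        if self.n_up is None or self.n_down is None:
            raise ValueError("give both n_up and n_down or neither")
        if self.n_de > self.p:
            raise ValueError("n_de cannot exceed p")
        if self.n_up + self.n_down != self.n_de:
            raise ValueError("n_up + n_down must equal n_de")
        k = len(_GROUP_NAMES[self.design])
        if self.n % k:
            raise ValueError(f"n={self.n} not divisible by {k} groups")
        for rate in (self.missing_rate, self.outlier_rate):
            if not 0 <= rate < 1:
                raise ValueError("rates must lie in [0, 1)")
        if not 0 <= self.mnar_fraction <= 1:
            raise ValueError("mnar_fraction must lie in [0, 1]")

    @property
    def group_labels(self) -> np.ndarray:
        names = _GROUP_NAMES[self.design]
        size = self.n // len(names)
        return np.repeat(names, size)


@dataclass
class SimulatedDataset:
    """Clean truth, contaminated observation, and the provenance masks."""

    clean: np.ndarray
    observed: np.ndarray  # NaN at missing cells
    de_labels: np.ndarray  # per-metabolite: "EE" / "up" / "down"
    groups: np.ndarray
    missing_mask: np.ndarray
    outlier_mask: np.ndarray
    mu: np.ndarray
    config: SimulationConfig

    def annotated(self, with_groups: bool = True) -> AnnotatedMatrix:
        """The observed matrix as an :class:`AnnotatedMatrix`."""
        groups = self.groups if with_groups and self.config.design != "no_class" else None
        return AnnotatedMatrix(
            values=self.observed.copy(),
            missing_mask=self.missing_mask.copy(),
            groups=groups,
        )

    @property
    def de_truth(self) -> np.ndarray:
        return self.de_labels != "EE"


def generate_clean(cfg: SimulationConfig, rng=None) -> SimulatedDataset:
    """Draw a clean (uncontaminated) dataset from the additive model."""
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    p, n = cfg.p, cfg.n
    mu = rng.uniform(5.0, 10.0, size=p)

    de_labels = np.array(["EE"] * p, dtype=object)
    de_labels[: cfg.n_up] = "up"
    de_labels[cfg.n_up : cfg.n_up + cfg.n_down] = "down"

    groups = cfg.group_labels
    m = np.zeros((p, n))
    if cfg.design != "no_class":
        means = _EFFECT_MEANS[cfg.design]
        names = _GROUP_NAMES[cfg.design]
        for gi, gname in enumerate(names):
            cols = groups == gname
            for lab in ("EE", "up", "down"):
                rows = de_labels == lab
                m[np.ix_(rows, cols)] = means[lab][gi]
    if cfg.zero_noise:
        clean = mu[:, None] + m
    else:
        g = rng.normal(m, 1.0)
        eps = rng.normal(0.0, 1.0, size=(p, n))
        clean = mu[:, None] + g + eps

    return SimulatedDataset(
        clean=clean,
        observed=clean.copy(),
        de_labels=np.asarray(de_labels, dtype="U4"),
        groups=np.asarray(groups, dtype=object),
        missing_mask=np.zeros((p, n), dtype=bool),
        outlier_mask=np.zeros((p, n), dtype=bool),
        mu=mu,
        config=cfg,
    )


def inject_missing(
    ds: SimulatedDataset,
    rate: float | None = None,
    mnar_fraction: float | None = None,
    rng=None,
) -> SimulatedDataset:
    """Mask ``round(rate·p·n)`` cells: an MCAR share chosen uniformly and an
    MNAR share sampled from the lowest decile of each metabolite (metabolites
    cycled until the quota is met).  No cell is selected twice."""
    cfg = ds.config
    rate = cfg.missing_rate if rate is None else rate
    mnar_fraction = cfg.mnar_fraction if mnar_fraction is None else mnar_fraction
    rng = np.random.default_rng(cfg.seed + 1 if rng is None else rng)
    p, n = ds.clean.shape
    m_total = round(rate * p * n)
    if m_total == 0:
        return ds
    m_mnar = round(mnar_fraction * m_total)
    m_mcar = m_total - m_mnar

    missing = ds.missing_mask.copy()
    flat_candidates = np.flatnonzero(~missing.ravel())
    mcar_cells = rng.choice(flat_candidates, size=m_mcar, replace=False)
    missing.ravel()[mcar_cells] = True

    # MNAR: lowest-decile cells per metabolite, metabolites cycled round-robin
    n_low = max(1, math.ceil(n / 10))
    order = np.argsort(ds.clean, axis=1)[:, :n_low]  # column indices of low cells
    low_pools = [list(rng.permutation(order[i])) for i in range(p)]
    quota = m_mnar
    row_cycle = rng.permutation(p)
    guard = 0
    while quota > 0:
        progressed = False
        for i in row_cycle:
            if quota == 0:
                break
            pool = low_pools[i]
            while pool:
                j = pool.pop()
                if not missing[i, j]:
                    missing[i, j] = True
                    quota -= 1
                    progressed = True
                    break
        if not progressed:
            raise ValueError("not enough low-decile cells to satisfy the MNAR quota")
        guard += 1
        if guard > n:  # pragma: no cover - defensive
            raise RuntimeError("MNAR selection failed to terminate")

    if missing.all(axis=1).any() or missing.all(axis=0).any():
        raise ValueError(
            "missing rate too high: a metabolite or sample lost all observations"
        )
    observed = ds.observed.copy()
    observed[missing] = np.nan
    return dataclasses.replace(ds, observed=observed, missing_mask=missing)


def inject_outliers(
    ds: SimulatedDataset, rate: float | None = None, rng=None
) -> SimulatedDataset:
    """Replace ``round(rate·p·n)`` randomly chosen observed cells by draws
    from N(5·mu_i, sigma_i²) of the clean metabolite row."""
    cfg = ds.config
    rate = cfg.outlier_rate if rate is None else rate
    rng = np.random.default_rng(cfg.seed + 2 if rng is None else rng)
    p, n = ds.clean.shape
    n_out = round(rate * p * n)
    if n_out == 0:
        return ds
    candidates = np.flatnonzero(~ds.missing_mask.ravel())
    if n_out > candidates.size:
        raise ValueError("outlier rate exceeds the number of observed cells")
    cells = rng.choice(candidates, size=n_out, replace=False)
    ri, ci = np.unravel_index(cells, (p, n))
    row_mean = ds.clean.mean(axis=1)
    row_std = ds.clean.std(axis=1)
    draws = rng.normal(5.0 * row_mean[ri], row_std[ri])
    observed = ds.observed.copy()
    observed[ri, ci] = draws
    outlier_mask = ds.outlier_mask.copy()
    outlier_mask[ri, ci] = True
    return dataclasses.replace(ds, observed=observed, outlier_mask=outlier_mask)


def generate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Clean draw + missingness + outliers, all seeded from ``cfg.seed``."""
    ss = np.random.SeedSequence(cfg.seed)
    s_clean, s_miss, s_out = ss.spawn(3)
    ds = generate_clean(cfg, rng=np.random.default_rng(s_clean))
    ds = inject_missing(ds, rng=np.random.default_rng(s_miss))
    ds = inject_outliers(ds, rng=np.random.default_rng(s_out))
    return ds


def generate_benchmark_suite(
    designs: Sequence[Design] = ("two_class",),
    missing_rates: Sequence[float] = (0.05,),
    outlier_rates: Sequence[float] = (0.0,),
    n_reps: int = 1,
    seed: int = 0,
    **cfg_kwargs,
) -> Iterator[SimulatedDataset]:
    """Deterministic cartesian grid of configurations × replicates.

    Per-replicate seeds are spawned from the master seed, so the same master
    seed regenerates the identical suite and distinct replicates differ.
    """
    ss = np.random.SeedSequence(seed)
    n_conditions = len(designs) * len(missing_rates) * len(outlier_rates)
    children = ss.spawn(n_conditions * n_reps)
    idx = 0
    for design in designs:
        for mr in missing_rates:
            for orate in outlier_rates:
                for _rep in range(n_reps):
                    child_seed = int(children[idx].generate_state(1)[0] % (2**31))
                    idx += 1
                    cfg = SimulationConfig(
                        design=design,
                        missing_rate=mr,
                        outlier_rate=orate,
                        seed=child_seed,
                        **cfg_kwargs,
                    )
                    yield generate_dataset(cfg)
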