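"""Station-level population summaries.

Responsive-unit fractions with bootstrap percentile confidence intervals
(resampling either units or whole animals with replacement — the latter is
the default for multi-site array data, where units recorded in one animal
are not independent), characteristic-frequency histograms on a log axis,
and one-way ANOVA across animals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .signal_io import ParameterError

log = logging.getLogger(__name__)


@dataclass
class PopulationSummary:
    station: str
    n_total: int
    n_responsive: int
    fraction: float
    ci95: tuple[float, float]
    resampling: str
    n_boot: int
    seed: int

    @property
    def percent(self) -> int:
        """Fraction as a rounded percentage."""
        return int(round(100.0 * self.fraction))

    @property
    def ci95_percent(self) -> tuple[int, int]:
        return int(round(100.0 * self.ci95[0])), int(round(100.0 * self.ci95[1]))


def fraction_responsive(
    flags,
    animal_ids=None,
    resampling: str = "unit",
    n_boot: int = 10000,
    seed: int = 0,
    station: str = "",
) -> PopulationSummary:
    """Responsive fraction with a bootstrap percentile 95% CI.

    ``resampling='unit'`` resamples units with replacement;
    ``resampling='animal'`` resamples animals with replacement, keeping
    each drawn animal's units together (clustered bootstrap).  CI bounds
    are the 2.5th/97.5th percentiles of the resampled fraction, with
    linear interpolation between order statistics.
    """
    flags = np.asarray(flags, dtype=bool)
    n = flags.size
    if n == 0:
        raise ParameterError("need at least one unit")
    rng = np.random.default_rng(seed)
    if resampling == "unit":
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = flags[idx].mean(axis=1)
    elif resampling == "animal":
        if animal_ids is None:
            raise ParameterError("animal-level resampling requires animal_ids")
        animal_ids = np.asarray(animal_ids)
        animals = np.unique(animal_ids)
        if animals.size < 2:
            raise ParameterError("animal-level resampling needs >= 2 animals")
        per_resp = np.array(
            [flags[animal_ids == a].sum() for a in animals], dtype=float
        )
        per_n = np.array(
            [(animal_ids == a).sum() for a in animals], dtype=float
        )
        pick = rng.integers(0, animals.size, size=(n_boot, animals.size))
        boots = per_resp[pick].sum(axis=1) / per_n[pick].sum(axis=1)
    else:
        raise ParameterError(f"unknown resampling mode {resampling!r}")
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return PopulationSummary(
        station=station,
        n_total=n,
        n_responsive=int(flags.sum()),
        fraction=float(flags.mean()),
        ci95=(float(lo), float(hi)),
        resampling=resampling,
        n_boot=n_boot,
        seed=seed,
    )


def cf_histogram(
    cfs_khz,
    bin_oct: float = 1.0 / 3.0,
    freq_range_khz: tuple[float, float] = (2.0, 90.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of characteristic frequencies in log-spaced bins.

    Returns ``(counts, bin_edges_khz)``.  Undefined CFs (None/NaN) are
    excluded with a logged count; counts sum to the number of defined CFs.
    """
    vals = np.array(
        [np.nan if c is None else float(c) for c in cfs_khz], dtype=float
    )
    defined = vals[np.isfinite(vals)]
    n_undef = vals.size - defined.size
    if n_undef:
        log.info("excluded %d undefined CF(s) from the histogram", n_undef)
    lo, hi = freq_range_khz
    n_bins = int(np.ceil(np.log2(hi / lo) / bin_oct))
    edges = lo * 2.0 ** (bin_oct * np.arange(n_bins + 1))
    edges[-1] = max(edges[-1], hi)
    counts, _ = np.histogram(np.clip(defined, lo, hi), bins=edges)
    return counts, edges


def anova_across_groups(groups, log2_transform: bool = False) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across groups (e.g. animals).

    ``groups`` is a mapping or sequence of per-group value arrays; groups
    with fewer than 2 values are dropped with a warning.  With
    ``log2_transform``, values (e.g. CFs in kHz) are log2-transformed
    first.  Returns ``(F, p)``.
    """
    if isinstance(groups, dict):
        groups = list(groups.values())
    arrs = []
    for g in groups:
        a = np.asarray(g, dtype=float)
        if a.size < 2:
            log.warning("dropping a group with %d value(s) from the ANOVA", a.size)
            continue
        arrs.append(np.log2(a) if log2_transform else a)
    if len(arrs) < 2:
        raise ParameterError("ANOVA needs >= 2 groups with >= 2 values each")
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p)
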