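"""Exact Mann-Whitney U and the Monte-Carlo fraction-of-significant-runs test.

Five serrations are measured per feather-position, but neighbouring
serrations are densely packed and do not vary independently, so the 25
values of a species-position cell are not 25 independent observations.
The resampling procedure deals with this: in each Monte-Carlo run one value
is drawn per feather (giving two independent samples of ``n_feathers``),
an exact two-sided Mann-Whitney U test is applied, and significance at
``alpha`` is recorded.  The summary statistic of a comparison is the
fraction of 5000 runs that came out significant, banded as

    ***  fraction > 0.99
    **   0.95 < fraction <= 0.99
    *    0.67 < fraction <= 0.95
    ns   fraction <= 0.67

(band edges fall in the lower band: "more than" is read strictly).

The U test is exact by full enumeration of all C(n_a + n_b, n_a) group
assignments of the pooled values, with midranks for ties; the two-sided
p-value is the proportion of assignments whose U is at least as far from
the null mean n_a*n_b/2 as the observed one.  For two samples of five this
is the classical 252-assignment permutation distribution; the smallest
achievable p is 2/252 (complete separation) and the exact size of the
nominal-0.05 test is 8/252.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MCSettings",
    "GroupKey",
    "ComparisonResult",
    "ComparisonScheme",
    "SCHEME_MODES",
    "exact_mann_whitney",
    "mc_comparison",
    "significance_band",
    "build_comparison_scheme",
    "run_all_comparisons",
]

_MAX_EXACT_N = 10


@dataclass(frozen=True)
class MCSettings:
    """Monte-Carlo procedure settings: 5000 runs at p < 0.05 by default."""

    n_runs: int = 5000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError(f"n_runs must be >= 1, got {self.n_runs}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


class GroupKey(NamedTuple):
    """Identifies one compared group: a species-position cell."""

    species: str
    position: float


@dataclass(frozen=True)
class ComparisonResult:
    group_a: GroupKey
    group_b: GroupKey
    parameter: str
    fraction_significant: float
    band: str
    n_runs: int


@lru_cache(maxsize=32)
def _assignment_matrix(n_a: int, n_b: int) -> np.ndarray:
    """0/1 indicator matrix (C(n_a+n_b, n_a) x (n_a+n_b)) of which pooled
    positions fall into group A, for every group assignment."""
    n = n_a + n_b
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), n_a)),
        dtype=np.intp,
    ).reshape(-1, n_a)
    m = np.zeros((combos.shape[0], n), dtype=float)
    np.put_along_axis(m, combos, 1.0, axis=1)
    return m


def _validate_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if arr.size > _MAX_EXACT_N:
        raise ValueError(f"{name} has {arr.size} values; exact test supports <= {_MAX_EXACT_N}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def exact_mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Exact two-sided Mann-Whitney p by full assignment enumeration.

    Ties are handled with midranks inside the enumeration, which keeps the
    test a valid permutation test for discrete or rounded data.
    """
    a = _validate_sample(sample_a, "sample_a")
    b = _validate_sample(sample_b, "sample_b")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    m = _assignment_matrix(n_a, n_b)
    u_all = m @ ranks - n_a * (n_a + 1) / 2.0
    center = n_a * n_b / 2.0
    stat_all = np.abs(u_all - center)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    stat_obs = abs(u_obs - center)
    # rank sums are multiples of 1/2, exactly representable; the small
    # tolerance only guards against accumulated matmul rounding
    return float(np.mean(stat_all >= stat_obs - 1e-9))


def significance_band(fraction: float) -> str:
    """Band a fraction of significant runs (***, **, *, ns)."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if fraction > 0.99:
        return "***"
    if fraction > 0.95:
        return "**"
    if fraction > 0.67:
        return "*"
    return "ns"


def _as_feather_matrix(group, name: str) -> np.ndarray:
    arr = np.asarray(group, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{name} must be a (n_feathers, n_serrations) matrix")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def mc_comparison(
    group_a,
    group_b,
    settings: MCSettings = MCSettings(),
    *,
    rng: np.random.Generator | None = None,
    group_a_key: GroupKey | None = None,
    group_b_key: GroupKey | None = None,
    parameter: str = "",
) -> ComparisonResult:
    """Monte-Carlo comparison of two species-position cells.

    ``group_a`` / ``group_b``: per-feather value sets, shape
    (n_feathers, n_serrations).  Each run draws one value per feather per
    group and applies the exact Mann-Whitney test; the result records the
    fraction of runs significant at ``settings.alpha`` and its band.
    """
    a = _as_feather_matrix(group_a, "group_a")
    b = _as_feather_matrix(group_b, "group_b")
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a + n_b > 2 * _MAX_EXACT_N:
        raise ValueError("too many feathers for the exact test")
    if rng is None:
        rng = np.random.default_rng(settings.seed)

    idx_a = rng.integers(0, a.shape[1], size=(settings.n_runs, n_a))
    idx_b = rng.integers(0, b.shape[1], size=(settings.n_runs, n_b))
    samples = np.concatenate(
        [a[np.arange(n_a), idx_a], b[np.arange(n_b), idx_b]], axis=1
    )
    ranks = rankdata(samples, axis=1)
    m = _assignment_matrix(n_a, n_b)
    center = n_a * n_b / 2.0
    offset = n_a * (n_a + 1) / 2.0
    stat_all = np.abs(ranks @ m.T - offset - center)
    stat_obs = np.abs(ranks[:, :n_a].sum(axis=1) - offset - center)
    p = np.mean(stat_all >= stat_obs[:, None] - 1e-9, axis=1)
    fraction = float(np.mean(p < settings.alpha))
    return ComparisonResult(
        group_a=group_a_key or GroupKey("A", float("nan")),
        group_b=group_b_key or GroupKey("B", float("nan")),
        parameter=parameter,
        fraction_significant=fraction,
        band=significance_band(fraction),
        n_runs=settings.n_runs,
    )


SCHEME_MODES = (
    "same_activity_diurnal",
    "same_activity_nocturnal",
    "diff_activity_all",
    "diff_activity_diff_size",
    "within_species_positions",
)


@dataclass(frozen=True)
class ComparisonScheme:
    """Enumerated list of group pairs for one comparison mode."""

    mode: str
    positions: tuple[float, ...]
    pairs: tuple[tuple[GroupKey, GroupKey], ...]

    def __len__(self) -> int:
        return len(self.pairs)


def build_comparison_scheme(
    species_table,
    mode: str,
    positions: Sequence[float] = (0.2, 0.4),
) -> ComparisonScheme:
    """Enumerate the unordered species pairs of a comparison mode.

    Between-species modes cross the matching species pairs with each vane
    position; ``within_species_positions`` pairs the two positions inside
    each species.  For the 7-species study design at positions {0.2, 0.4}
    the modes yield 24 (different activity), 16 (different activity and
    different size), 12 (nocturnal pairs) and 6 (diurnal pairs)
    comparisons, and 7 within-species comparisons.
    """
    if mode not in SCHEME_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {SCHEME_MODES}")
    species = list(species_table)
    positions = tuple(positions)
    pairs: list[tuple[GroupKey, GroupKey]] = []
    if mode == "within_species_positions":
        if len(positions) != 2:
            raise ValueError("within_species_positions requires exactly two positions")
        lo, hi = sorted(positions)
        for sp in species:
            pairs.append((GroupKey(sp.name, lo), GroupKey(sp.name, hi)))
        return ComparisonScheme(mode, positions, tuple(pairs))

    for i, a in enumerate(species):
        for b in species[i + 1:]:
            if mode == "same_activity_diurnal":
                keep = a.activity == "diurnal" and b.activity == "diurnal"
            elif mode == "same_activity_nocturnal":
                keep = a.activity == "nocturnal" and b.activity == "nocturnal"
            elif mode == "diff_activity_all":
                keep = a.activity != b.activity
            else:  # diff_activity_diff_size
                keep = a.activity != b.activity and a.size_class != b.size_class
            if keep:
                for pos in positions:
                    pairs.append((GroupKey(a.name, pos), GroupKey(b.name, pos)))
    return ComparisonScheme(mode, positions, tuple(pairs))


def _cell_matrix(dataset: pd.DataFrame, key: GroupKey, parameter: str) -> np.ndarray:
    cell = dataset[(dataset["species"] == key.species) & (dataset["position"] == key.position)]
    if cell.empty:
        raise ValueError(f"dataset has no measurements for ({key.species}, {key.position})")
    pivot = cell.pivot(index="feather_id", columns="serration_index", values=parameter)
    if pivot.isna().any().any():
        raise ValueError(
            f"incomplete feather blocks for ({key.species}, {key.position}): "
            "every feather needs the same serration indices"
        )
    return pivot.to_numpy()


def _pair_rng(seed: int, pair: tuple[GroupKey, GroupKey], parameter: str) -> np.random.Generator:
    """Per-comparison substream: stable under re-ordering or adding pairs."""
    tag = f"{pair[0].species}|{pair[0].position}|{pair[1].species}|{pair[1].position}|{parameter}"
    return np.random.default_rng(np.random.SeedSequence((seed, zlib.crc32(tag.encode()))))


def run_all_comparisons(
    dataset: pd.DataFrame,
    scheme: ComparisonScheme,
    parameter: str,
    settings: MCSettings = MCSettings(),
) -> list[ComparisonResult]:
    """Run the Monte-Carlo comparison for every pair of a scheme."""
    if parameter not in dataset.columns:
        raise ValueError(f"dataset has no column {parameter!r}")
    results = []
    for pair in scheme.pairs:
        a = _cell_matrix(dataset, pair[0], parameter)
        b = _cell_matrix(dataset, pair[1], parameter)
        results.append(
            mc_comparison(
                a, b, settings,
                rng=_pair_rng(settings.seed, pair, parameter),
                group_a_key=pair[0], group_b_key=pair[1],
                parameter=parameter,
            )
        )
    return results
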