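"""Group statistics: Kruskal-Wallis with Monte-Carlo p-values, and the
CFSE specific-lysis readout.

The Kruskal-Wallis statistic uses midranks and the standard tie
correction:

    H = [ 12 / (N (N+1)) * sum_j R_j^2 / n_j  -  3 (N+1) ] / C
    C = 1 - sum_t (t^3 - t) / (N^3 - N)

where R_j is the rank sum of group j and t runs over tie-group sizes.  The
asymptotic p-value is the chi-square tail with g-1 degrees of freedom; the
Monte-Carlo p-value permutes group labels and uses the add-one estimator
(b + 1) / (B + 1), which can never return zero.

The in-vivo cytotoxicity readout is computed exactly as printed:
``%CFSE-high x 100 / %CFSE-low`` — 100 means no antigen-specific killing
and 0 complete elimination of the peptide-pulsed (CFSE-high) targets.
Note this runs opposite to the common "% specific lysis" convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

SMALL_GROUP_N = 5  # flag MC as the preferred p-value below this group size
_PERM_CHUNK = 2048


@dataclass
class GroupTable:
    """Per-animal measurements with a group label.

    Thin wrapper around a DataFrame with columns ``animal``, ``group``,
    ``value``; provides validated access for the rank tests.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = {"animal", "group", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"group table missing columns {sorted(missing)}")
        values = self.data["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("group table contains non-finite values")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroupTable":
        try:
            df = pd.read_csv(path)
        except pd.errors.ParserError as exc:
            raise ValidationError(f"cannot parse {path}: {exc}") from exc
        return cls(df)

    def group_values(self) -> dict[str, np.ndarray]:
        out = {}
        for name, sub in self.data.groupby("group", sort=True):
            out[str(name)] = sub["value"].to_numpy(dtype=float)
        return out


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p_asymptotic: float
    p_mc: float | None = None
    n_permutations: int | None = None
    mc_se: float | None = None
    seed: int | None = None
    small_sample_flag: bool = False

    def significant(self, alpha: float = 0.05) -> bool:
        p = self.p_mc if self.p_mc is not None else self.p_asymptotic
        return p < alpha


def _check_groups(groups: dict[str, np.ndarray]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValidationError(f"need >= 2 groups, got {len(groups)}")
    arrays = list(groups.values())
    for name, arr in groups.items():
        if arr.size < 2:
            raise ValidationError(f"group {name!r} has {arr.size} < 2 observations")
    return arrays


def _h_from_rank_sums(rank_sums: np.ndarray, sizes: np.ndarray, n: int,
                      tie_correction: float) -> np.ndarray:
    h = 12.0 / (n * (n + 1)) * np.sum(rank_sums ** 2 / sizes, axis=-1) - 3.0 * (n + 1)
    return h / tie_correction


def _rank_setup(arrays: list[np.ndarray]):
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)  # midranks
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_correction = 1.0 - np.sum(tie_counts ** 3 - tie_counts) / (n ** 3 - n)
    sizes = np.array([a.size for a in arrays], dtype=float)
    return ranks, sizes, n, tie_correction


def kruskal_wallis(table: GroupTable) -> KWResult:
    """Tie-corrected Kruskal-Wallis test with the chi-square p-value."""
    groups = table.group_values()
    arrays = _check_groups(groups)
    ranks, sizes, n, tie_correction = _rank_setup(arrays)
    if tie_correction <= 0:  # all observations identical
        return KWResult(H=0.0, df=len(arrays) - 1, p_asymptotic=1.0,
                        small_sample_flag=bool(sizes.min() < SMALL_GROUP_N))
    bounds = np.cumsum([0] + [a.size for a in arrays])
    rank_sums = np.array([
        ranks[bounds[i]:bounds[i + 1]].sum() for i in range(len(arrays))
    ])
    h = float(_h_from_rank_sums(rank_sums, sizes, n, tie_correction))
    h = max(h, 0.0)
    df = len(arrays) - 1
    return KWResult(
        H=h,
        df=df,
        p_asymptotic=float(sps.chi2.sf(h, df)),
        small_sample_flag=bool(sizes.min() < SMALL_GROUP_N),
    )


def kw_monte_carlo(
    table: GroupTable,
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> KWResult:
    """Kruskal-Wallis with a Monte-Carlo permutation p-value.

    Group labels are randomly reassigned ``n_permutations`` times (the
    ranks stay fixed, so each permutation only re-slices the rank vector);
    p_mc = (1 + #{H_perm >= H_obs}) / (1 + B).  Deterministic given
    ``seed``; the binomial standard error of p_mc is reported.
    """
    if n_permutations < 100:
        raise ValidationError("n_permutations must be >= 100")
    base = kruskal_wallis(table)
    groups = table.group_values()
    arrays = _check_groups(groups)
    ranks, sizes, n, tie_correction = _rank_setup(arrays)
    if tie_correction <= 0:
        return KWResult(H=0.0, df=base.df, p_asymptotic=1.0, p_mc=1.0,
                        n_permutations=n_permutations, mc_se=0.0, seed=seed,
                        small_sample_flag=base.small_sample_flag)

    bounds = np.cumsum([0] + [a.size for a in arrays])
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    tol = 1e-12 * max(1.0, abs(base.H))
    while done < n_permutations:
        b = min(_PERM_CHUNK, n_permutations - done)
        perm = rng.permuted(np.broadcast_to(ranks, (b, n)), axis=1)
        rank_sums = np.stack(
            [perm[:, bounds[i]:bounds[i + 1]].sum(axis=1) for i in range(len(arrays))],
            axis=-1,
        )
        h_perm = _h_from_rank_sums(rank_sums, sizes, n, tie_correction)
        exceed += int(np.sum(h_perm >= base.H - tol))
        done += b
    p_mc = (exceed + 1) / (n_permutations + 1)
    mc_se = float(np.sqrt(p_mc * (1 - p_mc) / n_permutations))
    return KWResult(
        H=base.H,
        df=base.df,
        p_asymptotic=base.p_asymptotic,
        p_mc=p_mc,
        n_permutations=n_permutations,
        mc_se=mc_se,
        seed=seed,
        small_sample_flag=base.small_sample_flag,
    )


@dataclass(frozen=True)
class LysisResult:
    """CFSE recovery percentages and the printed lysis value."""

    pct_cfse_high: float
    pct_cfse_low: float
    lysis_value: float


def specific_lysis(pct_hi: float, pct_low: float) -> LysisResult:
    """Cytolytic-activity readout: ``pct_hi * 100 / pct_low``."""
    for name, value in (("pct_hi", pct_hi), ("pct_low", pct_low)):
        if not (0 <= value <= 100):
            raise ValidationError(f"{name}={value} outside [0, 100]")
    if pct_low == 0:
        raise ZeroDivisionError("pct_low is 0; lysis value undefined")
    return LysisResult(
        pct_cfse_high=float(pct_hi),
        pct_cfse_low=float(pct_low),
        lysis_value=float(pct_hi) * 100.0 / float(pct_low),
    )
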