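"""Bi-choice preference quantification and the Quade randomized-block test.

Feeding preference is the proportion of (water-loss-corrected) leaf-disc
weight loss per plant relative to the replicate total; oviposition
preference is the proportion of egg batches per plant.  Replicate
proportions form a blocks-by-choices matrix analysed with the Quade
test, a rank-based randomized-block test that weights within-block
ranks by the ranked block ranges.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PreferenceDataset",
    "QuadeResult",
    "corrected_consumption",
    "read_preference",
    "preference_proportions",
    "quade_test",
]


@dataclass
class PreferenceDataset:
    """Per-replicate measurements for a k-choice assay.

    ``values[i, j]`` is the corrected consumption (mg) or egg-batch count
    of choice j in replicate i.
    """

    choices: tuple[str, ...]
    replicate_ids: tuple[str, ...]
    values: np.ndarray         # (b, k), >= 0
    mode: str = "feeding"      # or "oviposition"

    @property
    def b(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class QuadeResult:
    statistic: float
    df1: int
    df2: int
    p_value: float
    method: str = "f"              # "f", "exact", or "degenerate"
    degenerate: bool = False       # no between-choice variation at all
    concordant: bool = False       # A == B: F approximation undefined
    ties: bool = False


def corrected_consumption(before: float, after: float,
                          control_loss_fraction: float, *,
                          tolerance: float = 1e-9) -> float:
    """Leaf consumption net of evaporative water loss, floored at zero.

    ``consumption = before * (1 - control_loss_fraction) - after``.  A
    measured ``after`` above the expected water-only residual (beyond
    ``tolerance``) triggers a warning and is clamped to zero.
    """
    if not 0 <= control_loss_fraction < 1:
        raise ValueError("control_loss_fraction must be in [0, 1)")
    if before <= 0:
        raise ValueError("initial weight must be positive")
    consumption = before * (1.0 - control_loss_fraction) - after
    if consumption < -tolerance:
        warnings.warn(
            f"after-weight {after} exceeds expected residual "
            f"{before * (1 - control_loss_fraction):.6g}; clamping to 0",
            RuntimeWarning, stacklevel=2)
    return max(consumption, 0.0)


def read_preference(path, mode: str = "feeding") -> PreferenceDataset:
    """Read a preference CSV.

    Feeding columns: ``replicate,species,weight_before_mg,weight_after_mg,
    control_loss_fraction``; oviposition columns: ``replicate,plant,
    egg_batches``.
    """
    df = pd.read_csv(path, dtype={"replicate": str})
    if mode == "feeding":
        required = {"replicate", "species", "weight_before_mg",
                    "weight_after_mg", "control_loss_fraction"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing column(s): {sorted(missing)}")
        df["value"] = [
            corrected_consumption(b, a, c)
            for b, a, c in zip(df["weight_before_mg"], df["weight_after_mg"],
                               df["control_loss_fraction"])
        ]
        choice_col = "species"
    elif mode == "oviposition":
        required = {"replicate", "plant", "egg_batches"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing column(s): {sorted(missing)}")
        if (df["egg_batches"] < 0).any():
            raise ValueError("egg_batches must be non-negative")
        df["value"] = df["egg_batches"].astype(float)
        choice_col = "plant"
    else:
        raise ValueError("mode must be 'feeding' or 'oviposition'")
    wide = df.pivot_table(index="replicate", columns=choice_col,
                          values="value", aggfunc="sum")
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"replicate(s) missing a choice measurement: {bad}")
    return PreferenceDataset(
        choices=tuple(wide.columns),
        replicate_ids=tuple(wide.index),
        values=wide.to_numpy(dtype=float),
        mode=mode,
    )


def preference_proportions(dataset: PreferenceDataset, *,
                           require_all_nonzero: bool = False
                           ) -> tuple[np.ndarray, int]:
    """Per-replicate proportions (rows sum to 1) and the exclusion count.

    Replicates with a zero total are always excluded; with
    ``require_all_nonzero`` every choice must have been consumed (the
    stricter reading of a both-consumed rule).
    """
    v = dataset.values
    if require_all_nonzero:
        keep = (v > 0).all(axis=1)
    else:
        keep = v.sum(axis=1) > 0
    excluded = int((~keep).sum())
    kept = v[keep]
    if kept.shape[0] == 0:
        raise ValueError("no replicates left after exclusion")
    props = kept / kept.sum(axis=1, keepdims=True)
    return props, excluded


# ---------------------------------------------------------------------------
# Quade test

def _quade_stats(data: np.ndarray) -> tuple[float, float, np.ndarray, bool]:
    """Return (A, B, S-matrix, ties?) of the Quade construction."""
    b, k = data.shape
    r = np.apply_along_axis(stats.rankdata, 1, data)        # within-block mid-ranks
    ranges = data.max(axis=1) - data.min(axis=1)
    Q = stats.rankdata(ranges)                              # block-range mid-ranks
    S = Q[:, None] * (r - (k + 1) / 2.0)
    A = float((S**2).sum())
    B = float((S.sum(axis=0)**2).sum() / b)
    ties = (len(np.unique(ranges)) < b
            or any(len(np.unique(row)) < k for row in data))
    return A, B, S, ties


def quade_test(proportions: np.ndarray, *, method: str = "f",
               max_exact: int = 1 << 20,
               seed: int | None = 0) -> QuadeResult:
    """Quade randomized-block test on a blocks-by-choices matrix.

    ``method="f"`` uses the F approximation with (k-1, (b-1)(k-1))
    degrees of freedom; ``method="exact"`` enumerates all within-block
    permutations (falling back to seeded Monte Carlo above ``max_exact``
    arrangements).  Perfectly concordant data (A == B, F undefined)
    automatically fall back to the permutation p-value, flagged in the
    result; a constant matrix is degenerate with p = 1.
    """
    data = np.asarray(proportions, dtype=float)
    if data.ndim != 2:
        raise ValueError("proportions must be a 2-D matrix")
    b, k = data.shape
    if b < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 choices")
    df1, df2 = k - 1, (b - 1) * (k - 1)
    A, B, S, ties = _quade_stats(data)
    if A <= 0:
        return QuadeResult(statistic=0.0, df1=df1, df2=df2, p_value=1.0,
                           method="degenerate", degenerate=True, ties=ties)
    concordant = math.isclose(A, B, rel_tol=1e-12, abs_tol=1e-12)
    if method == "exact" or concordant:
        p = _permutation_pvalue(data, B, max_exact, seed)
        statistic = math.inf if concordant else (b - 1) * B / (A - B)
        return QuadeResult(statistic=statistic, df1=df1, df2=df2, p_value=p,
                           method="exact", concordant=concordant, ties=ties)
    statistic = (b - 1) * B / (A - B)
    p = float(stats.f.sf(statistic, df1, df2))
    return QuadeResult(statistic=statistic, df1=df1, df2=df2, p_value=p,
                       method="f", concordant=False, ties=ties)


def _permutation_pvalue(data: np.ndarray, B_obs: float, max_exact: int,
                        seed: int | None) -> float:
    """P(B_perm >= B_obs) over within-block rearrangements.

    A and the block weights Q are invariant under within-block
    permutation, so the F statistic is monotone in B and the comparison
    can be made on B directly (robust when A == B makes F infinite).
    """
    b, k = data.shape
    n_arrangements = math.factorial(k) ** b
    perms = list(itertools.permutations(range(k)))
    if n_arrangements <= max_exact:
        count = 0
        total = 0
        for combo in itertools.product(range(len(perms)), repeat=b):
            permuted = np.empty_like(data)
            for i, pi in enumerate(combo):
                permuted[i] = data[i, perms[pi]]
            _, B_perm, _, _ = _quade_stats(permuted)
            if B_perm >= B_obs - 1e-12:
                count += 1
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    n_mc = 10_000
    count = 1   # add-one: the observed arrangement
    for _ in range(n_mc):
        permuted = np.empty_like(data)
        for i in range(b):
            permuted[i] = data[i, perms[rng.integers(len(perms))]]
        _, B_perm, _, _ = _quade_stats(permuted)
        if B_perm >= B_obs - 1e-12:
            count += 1
    return count / (n_mc + 1)
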