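"""Summit-proximity cobinding counts and their significance.

Two peaks from different experiments "cobind" when their summits lie within
``d_s`` bp of one another (default 150).  Significance of an observed
cobinding count k between experiments with n and m peaks is assessed against
a null in which binding events fall independently into N genome-wide
accessible slots of width d_s: either a Poisson tail with rate
``lambda = n*m/N`` (the default — more conservative) or the exact
hypergeometric tail with population N.  Counts above expectation are tested
on the upper tail ("enriched"), counts below on the lower tail ("depleted"),
and p-values convert to signed scores ``-log10 p`` (enriched) /
``+log10 p`` (depleted).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .peaks import Experiment, ValidationError

__all__ = [
    "NullModel",
    "CobindingResult",
    "count_cobinding",
    "cobinding_mask",
    "estimate_N",
    "poisson_pvalue",
    "hypergeom_pvalue",
    "bonferroni",
    "bonferroni_factor",
    "score_from_p",
    "pairwise_cobinding",
    "all_pairs",
    "results_table",
    "P_FLOOR",
]

# p-values are floored here before taking log10 so scores stay finite
P_FLOOR = 1e-300

DEFAULT_D_S = 150
N_SOMATIC = 250_000
N_ESC = 500_000


@dataclass(frozen=True)
class NullModel:
    """Accessible-slot null: N genome-wide slots of width d_s open to binding.

    Defaults follow digital genomic footprinting totals: ~250,000 slots for
    somatic mammalian cell lines, ~500,000 for embryonic stem cells (whose
    nucleosome occupancy is markedly lower).  ``counted_from_bed`` instead
    takes N as the row count of a user-supplied accessible-regions BED.
    """

    N: int
    d_s: int = DEFAULT_D_S
    source: str = "user"

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValidationError(f"N must be >= 1, got {self.N}")
        if self.d_s < 1:
            raise ValidationError(f"d_s must be >= 1, got {self.d_s}")


@dataclass
class CobindingResult:
    """Pairwise cobinding statistics for one ordered experiment pair."""

    exp_a: str
    exp_b: str
    factor_a: str
    factor_b: str
    n: int
    m: int
    k: int
    lam: float
    p_raw: float
    direction: str
    p_corrected: float
    score: float
    pairs: list[tuple[int, int]] = field(default_factory=list, repr=False)


def estimate_N(
    mode: str,
    bed: str | os.PathLike | None = None,
    d_s: int = DEFAULT_D_S,
) -> NullModel:
    """Estimate the number of accessible slots N for the null model.

    ``default_somatic`` -> 250,000; ``default_esc`` -> 500,000;
    ``counted_from_bed`` -> number of rows of ``bed`` (one slot per row, with
    a warning if any row's width differs from ``d_s``).
    """
    if mode == "default_somatic":
        if bed is not None:
            raise ValidationError("bed is only accepted with mode='counted_from_bed'")
        return NullModel(N=N_SOMATIC, d_s=d_s, source="default_somatic")
    if mode == "default_esc":
        if bed is not None:
            raise ValidationError("bed is only accepted with mode='counted_from_bed'")
        return NullModel(N=N_ESC, d_s=d_s, source="default_esc")
    if mode == "counted_from_bed":
        if bed is None:
            raise ValidationError("mode='counted_from_bed' requires a BED file")
        df = pd.read_csv(
            bed, sep="\t", header=None, usecols=[0, 1, 2], comment="#",
            names=["chrom", "start", "end"],
        )
        if len(df) == 0:
            raise ValidationError(f"accessible-regions BED {bed} is empty")
        widths = df["end"].to_numpy() - df["start"].to_numpy()
        if (widths != d_s).any():
            warnings.warn(
                f"{int((widths != d_s).sum())} of {len(df)} accessible regions "
                f"have width != d_s ({d_s} bp)",
                stacklevel=2,
            )
        return NullModel(N=len(df), d_s=d_s, source="counted_from_bed")
    raise ValidationError(f"unknown N-estimation mode {mode!r}")


def _nearest_partner(sa: np.ndarray, sb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each position in sorted sa, the nearest position in sorted sb.

    Returns (partner positions, distances).  Equidistant candidates resolve
    toward the lower coordinate.
    """
    idx = np.searchsorted(sb, sa)
    left = np.clip(idx - 1, 0, len(sb) - 1)
    right = np.clip(idx, 0, len(sb) - 1)
    dl = np.abs(sa - sb[left])
    dr = np.abs(sb[right] - sa)
    take_left = dl <= dr
    partner = np.where(take_left, sb[left], sb[right])
    dist = np.where(take_left, dl, dr)
    return partner, dist


def cobinding_mask(
    a: Experiment, b: Experiment, d_s: int = DEFAULT_D_S
) -> tuple[np.ndarray, np.ndarray]:
    """Per-peak cobinding of ``a`` against ``b``.

    Returns ``(mask, partners)`` aligned with a's global (chrom, summit)
    order: mask[i] is True when peak i of ``a`` has at least one summit of
    ``b`` on the same chromosome within ``d_s`` bp, and partners[i] is the
    nearest such summit (-1 where mask is False).
    """
    if d_s < 1:
        raise ValidationError(f"d_s must be >= 1, got {d_s}")
    mask = np.zeros(a.n_peaks, dtype=bool)
    partners = np.full(a.n_peaks, -1, dtype=np.int64)
    pos = 0
    for chrom in a.chrom_names:
        sa = a.summits(chrom)
        sb = b.summits(chrom)
        span = slice(pos, pos + len(sa))
        pos += len(sa)
        if len(sb) == 0 or len(sa) == 0:
            continue
        partner, dist = _nearest_partner(sa, sb)
        ok = dist <= d_s
        mask[span] = ok
        partners[span][ok] = partner[ok]
    return mask, partners


def count_cobinding(
    a: Experiment, b: Experiment, d_s: int = DEFAULT_D_S
) -> tuple[int, list[tuple[int, int]]]:
    """Count peaks of ``a`` whose summit has a summit of ``b`` within d_s bp.

    Each qualifying peak of ``a`` is paired with its nearest qualifying
    summit of ``b`` (ties toward the lower coordinate); matching is per
    chromosome on the sorted summit arrays.
    """
    mask, partners = cobinding_mask(a, b, d_s=d_s)
    summits = a.summit_positions
    pairs = [
        (int(summits[i]), int(partners[i])) for i in np.flatnonzero(mask)
    ]
    return int(mask.sum()), pairs


def poisson_pvalue(k: int, n: int, m: int, N: int) -> tuple[float, str]:
    """Poisson tail probability of k cobinding events, rate lambda = n*m/N.

    Returns ``(p, direction)``: the upper tail P(X >= k) with direction
    ``"enriched"`` when k >= lambda, the lower tail P(X <= k) with
    ``"depleted"`` otherwise.
    """
    if N <= 0:
        raise ValidationError(f"N must be positive, got {N}")
    if n < 0 or m < 0 or k < 0:
        raise ValidationError("k, n, m must be non-negative")
    if n * m == 0 and k > 0:
        raise ValidationError(f"k={k} > 0 with an empty experiment (n*m=0)")
    if k > min(n, m):
        raise ValidationError(f"k={k} exceeds min(n, m)={min(n, m)}")
    lam = n * m / N
    if k >= lam:
        p = float(sps.poisson.sf(k - 1, lam))  # P(X >= k)
        return max(p, P_FLOOR), "enriched"
    p = float(sps.poisson.cdf(k, lam))
    return max(p, P_FLOOR), "depleted"


def hypergeom_pvalue(k: int, n: int, m: int, N: int) -> tuple[float, str]:
    """Hypergeometric tail probability: population N, successes n, draws m.

    Direction is resolved against the mean n*m/N as in :func:`poisson_pvalue`.
    In the degenerate full-coverage case (single-point support, e.g. n = N)
    k is forced to the only supported value.
    """
    if N <= 0:
        raise ValidationError(f"N must be positive, got {N}")
    if n > N or m > N:
        raise ValidationError(f"n={n}, m={m} must not exceed N={N}")
    lo, hi = max(0, n + m - N), min(n, m)
    if lo == hi:
        k = lo
    elif not (lo <= k <= hi):
        raise ValidationError(f"k={k} outside hypergeometric support [{lo}, {hi}]")
    mean = n * m / N
    if k >= mean:
        p = float(sps.hypergeom.sf(k - 1, N, n, m))
        return min(max(p, P_FLOOR), 1.0), "enriched"
    p = float(sps.hypergeom.cdf(k, N, n, m))
    return min(max(p, P_FLOOR), 1.0), "depleted"


def bonferroni_factor(T: int, pairs: bool = False) -> int:
    """Multiple-testing factor for T experiments: T^2 (or T(T-1)/2 if pairs)."""
    if T < 1:
        raise ValidationError(f"T must be >= 1, got {T}")
    return T * (T - 1) // 2 if pairs else T * T

def bonferroni(p: float, T: int, pairs: bool = False) -> float:
    """Bonferroni correction over all T^2 ordered pairwise comparisons.

    The default multiplies by T*T (all ordered comparisons, the conservative
    convention); ``pairs=True`` uses T*(T-1)/2 unordered pairs instead.
    Capped at 1.
    """
    if not 0 < p <= 1:
        raise ValidationError(f"p must be in (0, 1], got {p}")
    return min(1.0, p * bonferroni_factor(T, pairs=pairs))


def score_from_p(p: float, direction: str) -> float:
    """Signed coassociation score: -log10 p if enriched, +log10 p if depleted."""
    p = min(max(p, P_FLOOR), 1.0)
    s = -np.log10(p)
    return float(s if direction == "enriched" else -s)


def pairwise_cobinding(
    a: Experiment,
    b: Experiment,
    null: NullModel,
    T: int,
    model: str = "poisson",
) -> CobindingResult:
    """Full pairwise cobinding test: count, p-value, correction and score."""
    if model not in ("poisson", "hypergeom"):
        raise ValidationError(f"unknown model {model!r}")
    k, pairs = count_cobinding(a, b, d_s=null.d_s)
    n, m = a.n_peaks, b.n_peaks
    if k > min(n, m):
        # many-to-one matches can in principle push the anchored count past m
        warnings.warn(
            f"cobinding count k={k} exceeds min(n, m); capping", stacklevel=2
        )
        k = min(n, m)
    pfun = poisson_pvalue if model == "poisson" else hypergeom_pvalue
    p_raw, direction = pfun(k, n, m, null.N)
    p_raw = max(p_raw, P_FLOOR)
    return CobindingResult(
        exp_a=a.id,
        exp_b=b.id,
        factor_a=a.factor,
        factor_b=b.factor,
        n=n,
        m=m,
        k=k,
        lam=n * m / null.N,
        p_raw=p_raw,
        direction=direction,
        p_corrected=bonferroni(p_raw, T),
        score=score_from_p(p_raw, direction),
        pairs=pairs,
    )


def all_pairs(
    experiments: Sequence[Experiment],
    null: NullModel,
    model: str = "poisson",
    T: int | None = None,
) -> list[CobindingResult]:
    """Cobinding results for every ordered pair of distinct experiments.

    T defaults to the number of experiments, giving the T^2 Bonferroni
    convention over all pairwise comparisons.
    """
    if T is None:
        T = len(experiments)
    out = []
    for a in experiments:
        for b in experiments:
            if a.id != b.id:
                out.append(pairwise_cobinding(a, b, null, T=T, model=model))
    return out


def results_table(results: Iterable[CobindingResult]) -> pd.DataFrame:
    """Tabulate cobinding results (one row per ordered pair)."""
    cols = [
        "exp_a", "exp_b", "factor_a", "factor_b", "n", "m", "k",
        "lam", "p_raw", "direction", "p_corrected", "score",
    ]
    rows = [{c: getattr(r, c) for c in cols} for r in results]
    df = pd.DataFrame(rows, columns=cols)
    return df.rename(columns={"lam": "lambda"})
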