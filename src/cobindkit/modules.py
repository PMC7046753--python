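"""Module discovery: score matrices, clustering, and conditional cobinding.

Pairwise signed scores (+/- log10 p) over all experiments form a square
coassociation matrix whose clustered heatmap exposes candidate regulatory
modules.  Choosing a "base" TF then refines pairs into triplets: within the
k_b peaks of the base, two other factors with k_i and k_j base-cobinding
regions are expected to co-occur on ``lambda = k_i * k_j / k_b`` base peaks
by chance, and the observed joint count k_ij is tested with the same Poisson
tails as the pairwise layer.  Iterating — shrinking the base to the current
joint cobinding-region set and testing one more factor against it — extends
modules to quadruplets and beyond.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .peaks import Experiment, ValidationError
from .stats import (
    DEFAULT_D_S,
    P_FLOOR,
    CobindingResult,
    NullModel,
    cobinding_mask,
    pairwise_cobinding,
    score_from_p,
)

__all__ = [
    "ScoreMatrix",
    "ConditionalResult",
    "ClusterTree",
    "build_score_matrix",
    "cluster_scores",
    "conditional_cobinding",
    "conditional_score_matrix",
    "iterate_module",
    "conditional_heatmap",
    "conditional_table",
    "plot_heatmap",
]


@dataclass
class ScoreMatrix:
    """Square matrix of signed coassociation scores with experiment ids.

    Symmetrized by averaging the two counting orientations; the diagonal is
    defined as 0.
    """

    ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("score matrix shape does not match ids")
        if not np.isfinite(self.scores).all():
            raise ValidationError("score matrix contains non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.ids, columns=self.ids)

    def write(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class ConditionalResult:
    """Triplet test: cobinding of tf_i and tf_j within the base TF's peaks.

    ``tf_j`` is None for iterated (module-extension) tests of a single
    candidate against a current cobinding-region set, where the expected
    count is the pairwise ``k_b * n_candidate / N`` instead.
    """

    base: str
    tf_i: str
    tf_j: str | None
    k_b: int
    k_i: int
    k_j: int | None
    k_ij: int
    lam: float
    p_raw: float
    direction: str
    p_corrected: float
    score: float


@dataclass
class ClusterTree:
    """Hierarchical clustering of a score matrix (Pearson distance)."""

    linkage: np.ndarray
    labels: np.ndarray
    order: np.ndarray
    flagged: list[str] = field(default_factory=list)


def build_score_matrix(
    results: Sequence[CobindingResult], ids: Sequence[str] | None = None
) -> ScoreMatrix:
    """Assemble the symmetrized score matrix from all ordered-pair results.

    Entry (i, j) is the mean of the two orientation scores; every ordered
    pair over the id set must be present.
    """
    by_pair = {(r.exp_a, r.exp_b): r.score for r in results}
    if ids is None:
        ids = sorted({i for pair in by_pair for i in pair})
    ids = list(ids)
    n = len(ids)
    M = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i == j:
                continue
            if (a, b) not in by_pair or (b, a) not in by_pair:
                raise ValidationError(f"missing cobinding result for pair ({a}, {b})")
            M[i, j] = 0.5 * (by_pair[(a, b)] + by_pair[(b, a)])
    return ScoreMatrix(ids=ids, scores=M)


def _pearson_distance(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1 - Pearson r between score rows; constant rows get distance 1."""
    n = M.shape[0]
    sd = M.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(M)
    D = 1.0 - R
    D[constant, :] = 1.0
    D[:, constant] = 1.0
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    return D, constant


def cluster_scores(
    M: ScoreMatrix,
    method: str = "average",
    cut: int | float | None = None,
) -> ClusterTree:
    """Hierarchically cluster score rows with 1 - Pearson r as distance.

    ``cut`` selects the flat clustering: an int is a cluster count
    (maxclust), a float a distance height; None keeps everything in one
    cluster.  Rows of zero variance get distance 1 to all others and are
    reported in ``flagged``.
    """
    if M.scores.shape[0] < 2:
        raise ValidationError("need at least 2 rows to cluster")
    D, constant = _pearson_distance(M.scores)
    Z = hierarchy.linkage(squareform(D, checks=False), method=method)
    if cut is None:
        labels = np.ones(len(M.ids), dtype=int)
    elif isinstance(cut, (int, np.integer)):
        labels = hierarchy.fcluster(Z, t=int(cut), criterion="maxclust")
    else:
        labels = hierarchy.fcluster(Z, t=float(cut), criterion="distance")
    order = hierarchy.leaves_list(Z)
    flagged = [M.ids[i] for i in np.flatnonzero(constant)]
    return ClusterTree(linkage=Z, labels=labels, order=order, flagged=flagged)


def _poisson_tail(k: int, lam: float) -> tuple[float, str]:
    if k >= lam:
        return max(float(sps.poisson.sf(k - 1, lam)), 0.0), "enriched"
    return max(float(sps.poisson.cdf(k, lam)), 0.0), "depleted"


def conditional_cobinding(
    base: Experiment,
    i: Experiment,
    j: Experiment,
    d_s: int = DEFAULT_D_S,
    n_tests: int = 1,
) -> ConditionalResult:
    """Test joint cobinding of i and j within the base TF's peaks.

    k_i (k_j) counts base peaks with a summit of i (j) within d_s; k_ij
    counts base peaks qualifying for both; expected k_ij under independence
    is ``lambda = k_i * k_j / k_b``.  ``n_tests`` is the Bonferroni family
    size (number of (i, j) pairs tested within this base).
    """
    k_b = base.n_peaks
    if k_b == 0:
        raise ValidationError("base experiment has no peaks")
    mask_i, _ = cobinding_mask(base, i, d_s=d_s)
    mask_j, _ = cobinding_mask(base, j, d_s=d_s)
    k_i = int(mask_i.sum())
    k_j = int(mask_j.sum())
    k_ij = int((mask_i & mask_j).sum())
    lam = k_i * k_j / k_b
    p_raw, direction = _poisson_tail(k_ij, lam)
    p_raw = max(p_raw, P_FLOOR)
    return ConditionalResult(
        base=base.id,
        tf_i=i.id,
        tf_j=j.id,
        k_b=k_b,
        k_i=k_i,
        k_j=k_j,
        k_ij=k_ij,
        lam=lam,
        p_raw=p_raw,
        direction=direction,
        p_corrected=min(1.0, p_raw * n_tests),
        score=score_from_p(p_raw, direction),
    )


def _joint_region_experiment(
    base_set: Sequence[Experiment], d_s: int
) -> Experiment:
    """Base peaks cobound by every non-base member of ``base_set``."""
    base = base_set[0]
    mask = np.ones(base.n_peaks, dtype=bool)
    for other in base_set[1:]:
        m, _ = cobinding_mask(base, other, d_s=d_s)
        mask &= m
    if not mask.any():
        raise ValidationError("current cobinding-region set is empty")
    return Experiment.from_summits(
        id="&".join(e.id for e in base_set),
        factor="+".join(e.factor for e in base_set),
        summits=base.summit_positions[mask],
        chrom=base.chroms[mask],
    )


def iterate_module(
    base_set: Sequence[Experiment],
    candidate: Experiment,
    null: NullModel,
    d_s: int | None = None,
) -> ConditionalResult:
    """Extend a module: test one more factor against the current region set.

    The peaks of base_set[0] cobound by every other member form the current
    cobinding-region set (size k_b'); the candidate's overlap count with it
    is tested against the expectation ``k_b' * n_candidate / N`` under
    uniform placement of the candidate's summits over the N accessible
    slots.  Iterating grows triplets into quadruplets and beyond.
    """
    if d_s is None:
        d_s = null.d_s
    regions = _joint_region_experiment(base_set, d_s)
    mask, _ = cobinding_mask(regions, candidate, d_s=d_s)
    k = int(mask.sum())
    lam = regions.n_peaks * candidate.n_peaks / null.N
    p_raw, direction = _poisson_tail(k, lam)
    p_raw = max(p_raw, P_FLOOR)
    return ConditionalResult(
        base=regions.id,
        tf_i=candidate.id,
        tf_j=None,
        k_b=regions.n_peaks,
        k_i=candidate.n_peaks,
        k_j=None,
        k_ij=k,
        lam=lam,
        p_raw=p_raw,
        direction=direction,
        p_corrected=p_raw,
        score=score_from_p(p_raw, direction),
    )


def conditional_score_matrix(
    base: Experiment,
    others: Sequence[Experiment],
    d_s: int = DEFAULT_D_S,
) -> tuple[ScoreMatrix, list[ConditionalResult]]:
    """All-pairs conditional scores of ``others`` within the base's peaks.

    Bonferroni family size is the number of unordered (i, j) pairs tested.
    """
    ids = [e.id for e in others]
    n = len(others)
    if n < 2:
        raise ValidationError("need at least 2 candidate experiments")
    n_tests = n * (n - 1) // 2
    M = np.zeros((n, n))
    results = []
    for a in range(n):
        for b in range(a + 1, n):
            r = conditional_cobinding(
                base, others[a], others[b], d_s=d_s, n_tests=n_tests
            )
            M[a, b] = M[b, a] = r.score
            results.append(r)
    return ScoreMatrix(ids=ids, scores=M), results


def conditional_heatmap(
    base: Experiment,
    others: Sequence[Experiment],
    null: NullModel,
    theta: float = 1e-10,
    method: str = "average",
    cut: int | float | None = None,
) -> tuple[ScoreMatrix, ClusterTree, list[ConditionalResult]]:
    """Conditional score matrix over factors pairwise-significant with base.

    Candidates are kept when their pairwise cobinding with the base is
    enriched with raw p < theta (default 1e-10; anchor-TF analyses in dense
    compendia often use 1e-100).  The filtered set is scored conditionally
    within the base's peaks and clustered with Pearson distance.
    """
    selected = []
    for e in others:
        r = pairwise_cobinding(base, e, null, T=1)
        if r.direction == "enriched" and r.p_raw < theta:
            selected.append(e)
    if len(selected) < 2:
        raise ValidationError(
            f"only {len(selected)} experiments pass the pairwise threshold "
            f"theta={theta:g} with base {base.id}; need at least 2"
        )
    M, results = conditional_score_matrix(base, selected, d_s=null.d_s)
    tree = cluster_scores(M, method=method, cut=cut)
    return M, tree, results


def conditional_table(results: Sequence[ConditionalResult]) -> pd.DataFrame:
    cols = [
        "base", "tf_i", "tf_j", "k_b", "k_i", "k_j", "k_ij",
        "lam", "p_raw", "direction", "p_corrected", "score",
    ]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)
    return df.rename(columns={"lam": "lambda"})


def plot_heatmap(
    M: ScoreMatrix, tree: ClusterTree | None = None, path: str | os.PathLike | None = None
):
    """Render the score matrix (blue = enriched, gray/black = depleted).

    Purely cosmetic; the tested contract is the matrix values.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = tree.order if tree is not None else np.arange(len(M.ids))
    S = M.scores[np.ix_(order, order)]
    ids = [M.ids[i] for i in order]
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("cobind", ["black", "white", "blue"])
    lim = max(1.0, np.abs(S).max())
    fig, ax = plt.subplots(figsize=(max(4, len(ids) * 0.3),) * 2)
    im = ax.imshow(S, cmap=cmap, vmin=-lim, vmax=lim)
    ax.set_xticks(range(len(ids)), ids, rotation=90, fontsize=6)
    ax.set_yticks(range(len(ids)), ids, fontsize=6)
    fig.colorbar(im, ax=ax, label="signed -log10 p")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
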