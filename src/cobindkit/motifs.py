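"""PWM scanning of summit-centered windows and motif arrangement analysis.

A position weight model (PWM, JASPAR-style frequency matrix) is scored on a
window by summing the per-position base frequencies of a candidate instance
and min/max-normalizing the sum to [0, 1]: the per-position argmax string
(consensus) scores exactly 1, the per-position argmin string 0.  For each
150-bp window centered on a peak summit the best-scoring instance over all
offsets and both strands is kept.

Three enrichment measures mirror how summit-centered motif analysis is
interpreted in practice:

* global enrichment — best-instance scores vs. scores in accessible genomic
  background windows (one-tailed two-sample z-test on the mean);
* local enrichment — summit windows vs. their immediate flanks (paired
  one-tailed z-test);
* positional bias — non-uniformity of best-instance positions within the
  window (chi-square against the discrete uniform over achievable offsets).

Motif-centered analysis re-anchors each region on the best instance of a
chosen motif (discarding regions where that instance is low-quality),
normalizes the anchor to the + strand, and records partner-motif distances
and strands, exposing fixed spacing/orientation rules between binding sites.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .peaks import ParseError, ValidationError

__all__ = [
    "PositionWeightModel",
    "RegionHit",
    "MotifEnrichmentReport",
    "MotifArrangement",
    "read_jaspar",
    "write_jaspar",
    "pwm_from_consensus",
    "load_genome",
    "fetch",
    "scan_sequences",
    "scan_regions",
    "global_enrichment",
    "local_enrichment",
    "positional_bias",
    "motif_centered_rescan",
    "enrichment_report",
    "interpret_pair",
]

DEFAULT_WINDOW = 150
BASES = "ACGT"
_BASE_IDX = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_IDX[ord(_b)] = _i
    _BASE_IDX[ord(_b.lower())] = _i
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 indices (A=0, C=1, G=2, T=3, other=4)."""
    return _BASE_IDX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class PositionWeightModel:
    """A 4xL count matrix with pseudocounted frequencies and [0,1] scoring.

    A pseudocount of 0.01 times the column total, split equally over the four
    bases, is added before column normalization.  Ambiguous bases score the
    column mean (0.25 after normalization).
    """

    def __init__(self, name: str, counts: np.ndarray) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValidationError(f"counts must be 4xL, got {counts.shape}")
        if counts.shape[1] < 4:
            raise ValidationError(f"motif length must be >= 4, got {counts.shape[1]}")
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            raise ValidationError("every column must have a positive total")
        self.name = name
        self.counts = counts
        pseudo = 0.01 * totals / 4.0
        freq = (counts + pseudo) / (totals * 1.01)
        self.frequencies = freq
        self.length = counts.shape[1]
        self._min = float(freq.min(axis=0).sum())
        self._max = float(freq.max(axis=0).sum())
        # row 4 = column mean, used for ambiguous bases
        self._ext = np.vstack([freq, freq.mean(axis=0)])
        self._ext_rc = self._ext[[3, 2, 1, 0, 4]][:, ::-1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.frequencies.argmax(axis=0))

    @property
    def anti_consensus(self) -> str:
        return "".join(BASES[i] for i in self.frequencies.argmin(axis=0))

    def normalize(self, raw: np.ndarray) -> np.ndarray:
        return np.clip((raw - self._min) / (self._max - self._min), 0.0, 1.0)

    def __repr__(self) -> str:
        return f"PositionWeightModel({self.name!r}, L={self.length})"


@dataclass(frozen=True)
class RegionHit:
    """Best motif instance in one scanned region."""

    region: int
    best_score: float
    offset: int
    strand: str
    center: int  # offset + L//2, in region coordinates (base-resolution)


@dataclass
class MotifEnrichmentReport:
    """Per-motif enrichment summary over a set of summit regions."""

    motif: str
    mean: float
    variance: float
    global_p: float
    global_p_bonferroni: float
    local_p: float
    positional_bias_p: float
    n_regions: int
    hits: list[RegionHit] = field(repr=False, default_factory=list)


@dataclass
class MotifArrangement:
    """Partner-motif placement relative to a strand-normalized anchor motif.

    Distances are center-to-center in bp, negative when the partner lies
    upstream of the anchor (after flipping regions so the anchor reads on
    the + strand).  Partner strands are reported relative to the anchor.
    """

    anchor: str
    partner: str
    distances: np.ndarray
    strands: np.ndarray
    histogram: pd.DataFrame  # columns: distance, strand, count
    modal_distances: list[int]
    positional_bias_p: float
    n_regions: int
    n_discarded: int


# ---------------------------------------------------------------------------
# JASPAR I/O

_JASPAR_ROW = re.compile(r"^([ACGTacgt])\s*\[?\s*([-\d.eE+\s]*?)\s*\]?\s*$")


def read_jaspar(path: str | os.PathLike) -> list[PositionWeightModel]:
    """Read motifs in JASPAR text format (">ID NAME" + 4 bracketed rows)."""
    pwms: list[PositionWeightModel] = []
    name = None
    rows: dict[str, list[float]] = {}

    def flush(lineno: int) -> None:
        nonlocal name, rows
        if name is None:
            return
        if set(rows) != set(BASES):
            raise ParseError(
                f"motif {name!r} before line {lineno}: expected rows A,C,G,T, "
                f"got {sorted(rows)}"
            )
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise ParseError(f"motif {name!r}: rows of unequal length {lengths}")
        pwms.append(PositionWeightModel(name, np.array([rows[b] for b in BASES])))
        name, rows = None, {}

    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                name = line[1:].strip()
                continue
            m = _JASPAR_ROW.match(line)
            if m is None or name is None:
                raise ParseError(f"line {lineno}: unparseable JASPAR row {line!r}")
            base = m.group(1).upper()
            if base in rows:
                raise ParseError(f"line {lineno}: duplicate row for base {base}")
            rows[base] = [float(t) for t in m.group(2).split()]
    flush(lineno + 1)
    return pwms


def write_jaspar(pwms: Sequence[PositionWeightModel], path: str | os.PathLike) -> None:
    """Write motifs in JASPAR text format; round-trips counts exactly."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for b, row in zip(BASES, pwm.counts):
                vals = " ".join(f"{v:g}" for v in row)
                fh.write(f"{b} [ {vals} ]\n")


def pwm_from_consensus(
    name: str, consensus: str, weight: float = 100.0, off: float = 1.0
) -> PositionWeightModel:
    """Build a sharp PWM whose consensus is the given string."""
    idx = encode(consensus)
    if (idx > 3).any():
        raise ValidationError(f"consensus {consensus!r} contains non-ACGT bases")
    counts = np.full((4, len(consensus)), off)
    counts[idx, np.arange(len(consensus))] = weight
    return PositionWeightModel(name, counts)


# ---------------------------------------------------------------------------
# Genome access

def load_genome(path: str | os.PathLike):
    """Open an (indexed) FASTA for random access."""
    from pyfaidx import Fasta

    return Fasta(os.fspath(path))


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Extract genome[chrom][start:end) from a pyfaidx Fasta or a plain dict."""
    seq = genome[chrom][start:end]
    return str(seq)


def chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


# ---------------------------------------------------------------------------
# Scanning

def _window_scores(X: np.ndarray, pwm: PositionWeightModel) -> tuple[np.ndarray, np.ndarray]:
    """Raw frequency-sum scores at every offset, both strands.

    X: (n_regions, W) encoded sequences. Returns (S_plus, S_minus) of shape
    (n_regions, W - L + 1).
    """
    L = pwm.length
    win = np.lib.stride_tricks.sliding_window_view(X, L, axis=1)
    pos = np.arange(L)
    S_plus = pwm._ext[win, pos].sum(axis=-1)
    S_minus = pwm._ext_rc[win, pos].sum(axis=-1)
    return S_plus, S_minus


def scan_sequences(
    seqs: Sequence[str] | np.ndarray,
    pwm: PositionWeightModel,
    strands: str = "+-",
) -> list[RegionHit]:
    """Best normalized motif instance per equal-length sequence.

    Ties resolve toward the + strand, then the lower offset; the reverse
    strand hit at offset o occupies [o, o+L) in forward coordinates.
    ``strands`` restricts the search ("+", "-", or the default both).
    """
    if isinstance(seqs, np.ndarray) and seqs.ndim == 2:
        X = seqs
    else:
        X = np.stack([encode(s) for s in seqs])
    if X.shape[1] < pwm.length:
        raise ValidationError(
            f"sequences of length {X.shape[1]} shorter than motif ({pwm.length})"
        )
    Sp, Sm = _window_scores(X, pwm)
    if strands == "+":
        Sm = np.full_like(Sm, -np.inf)
    elif strands == "-":
        Sp = np.full_like(Sp, -np.inf)
    elif strands != "+-":
        raise ValidationError(f"strands must be '+', '-' or '+-', got {strands!r}")
    op = Sp.argmax(axis=1)
    om = Sm.argmax(axis=1)
    bp = Sp[np.arange(len(X)), op]
    bm = Sm[np.arange(len(X)), om]
    # ties prefer +; the tolerance keeps mathematically tied scores (a k-mer
    # vs. its reverse complement, summed in different order) from being
    # broken by float rounding
    minus = bm > bp + 1e-9
    best = np.where(minus, bm, bp)
    offset = np.where(minus, om, op)
    norm = pwm.normalize(best)
    half = pwm.length // 2
    return [
        RegionHit(
            region=i,
            best_score=float(norm[i]),
            offset=int(offset[i]),
            strand="-" if minus[i] else "+",
            center=int(offset[i] + half),
        )
        for i in range(len(X))
    ]


def extract_windows(
    regions: Sequence[tuple[str, int]],
    genome,
    window: int = DEFAULT_WINDOW,
    shift: int = 0,
) -> tuple[np.ndarray, list[int]]:
    """Encoded ``window``-bp sequences centered on each (chrom, center).

    Windows extending past a chromosome end are skipped with a warning;
    returns (matrix, kept region indices).  ``shift`` moves every window
    center by a constant (used for flanks).
    """
    seqs = []
    kept = []
    half = window // 2
    for i, (chrom, center) in enumerate(regions):
        start = int(center) + shift - half
        end = start + window
        if start < 0 or end > chrom_length(genome, chrom):
            warnings.warn(
                f"region {i} ({chrom}:{center}) window [{start},{end}) out of "
                "bounds; skipped",
                stacklevel=2,
            )
            continue
        seqs.append(encode(fetch(genome, chrom, start, end)))
        kept.append(i)
    if not seqs:
        return np.empty((0, window), dtype=np.int8), []
    return np.stack(seqs), kept


def scan_regions(
    regions: Sequence[tuple[str, int]],
    genome,
    pwm: PositionWeightModel,
    window: int = DEFAULT_WINDOW,
) -> list[RegionHit]:
    """Best motif instance in the ``window`` bp centered on each summit."""
    X, kept = extract_windows(regions, genome, window=window)
    hits = scan_sequences(X, pwm) if len(X) else []
    return [
        RegionHit(
            region=kept[h.region],
            best_score=h.best_score,
            offset=h.offset,
            strand=h.strand,
            center=h.center,
        )
        for h in hits
    ]


# ---------------------------------------------------------------------------
# Enrichment statistics

def _one_tailed_z(delta_mean: float, se: float) -> float:
    if se == 0:
        if delta_mean > 0:
            return float(np.finfo(float).tiny)
        return 1.0 if delta_mean < 0 else 0.5
    p = float(sps.norm.sf(delta_mean / se))
    return min(max(p, np.finfo(float).tiny), 1.0)


def global_enrichment(
    hits: Sequence[RegionHit], background: Sequence[RegionHit]
) -> float:
    """One-tailed z-test: mean best score in regions vs. genomic background."""
    if len(background) < 200:
        raise ValidationError(
            f"background must have >= 200 regions, got {len(background)}"
        )
    x = np.array([h.best_score for h in hits])
    y = np.array([h.best_score for h in background])
    if x.std() == 0 and y.std() == 0:
        warnings.warn("zero variance in both samples; p = 1", stacklevel=2)
        return 1.0
    se = float(np.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y)))
    return _one_tailed_z(float(x.mean() - y.mean()), se)


def local_enrichment(
    regions: Sequence[tuple[str, int]],
    genome,
    pwm: PositionWeightModel,
    window: int = DEFAULT_WINDOW,
    flank: int | None = None,
) -> float:
    """Paired one-tailed z-test: summit windows vs. their two flanks.

    For each region the best score in the summit-centered window is compared
    with the mean of the best scores in the two adjacent windows of equal
    width immediately upstream and downstream.
    """
    if flank is None:
        flank = window
    shift = (window + flank) // 2
    X_c, kept_c = extract_windows(regions, genome, window=window)
    X_l, kept_l = extract_windows(regions, genome, window=flank, shift=-shift)
    X_r, kept_r = extract_windows(regions, genome, window=flank, shift=shift)
    common = sorted(set(kept_c) & set(kept_l) & set(kept_r))
    if len(common) < 2:
        raise ValidationError("fewer than 2 regions with both flanks in bounds")

    def scores(X, kept):
        sel = [kept.index(i) for i in common]
        hits = scan_sequences(X[sel], pwm)
        return np.array([h.best_score for h in hits])

    d = scores(X_c, kept_c) - 0.5 * (scores(X_l, kept_l) + scores(X_r, kept_r))
    se = float(d.std(ddof=1) / np.sqrt(len(d)))
    return _one_tailed_z(float(d.mean()), se)


def positional_bias(
    hits: Sequence[RegionHit],
    n_offsets: int | None = None,
    bins: int = 15,
) -> float:
    """Chi-square test of best-instance positions against discrete uniform.

    ``n_offsets`` is the number of achievable instance start offsets
    (window - L + 1); inferred from the data when omitted.  Expected bin
    counts follow the exact number of integer offsets per bin, so the test
    is calibrated on the true support.  With fewer regions than requested
    bins the bin count is reduced to max(5, n_regions // 10).
    """
    offsets = np.array([h.offset for h in hits])
    n = len(offsets)
    if n == 0:
        raise ValidationError("no hits to test")
    if n_offsets is None:
        n_offsets = int(offsets.max()) + 1
    if n < bins:
        bins = max(5, n // 10)
        warnings.warn(f"fewer regions than bins; reduced to {bins} bins", stacklevel=2)
    bins = min(bins, n_offsets)
    edges = np.linspace(0, n_offsets, bins + 1)
    observed, _ = np.histogram(offsets, bins=edges)
    # exact discrete-uniform expectation: count of integer offsets per bin
    ints = np.arange(n_offsets)
    per_bin, _ = np.histogram(ints, bins=edges)
    expected = per_bin / n_offsets * n
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df=bins - 1))
    return min(max(p, np.finfo(float).tiny), 1.0)


# ---------------------------------------------------------------------------
# Motif-centered analysis

def motif_centered_rescan(
    regions: Sequence[tuple[str, int]],
    genome,
    anchor_pwm: PositionWeightModel,
    partner_pwms: Sequence[PositionWeightModel],
    window: int = DEFAULT_WINDOW,
    quality_threshold: float = 0.8,
) -> dict[str, MotifArrangement]:
    """Re-anchor regions on the anchor motif's best instance, scan partners.

    Regions whose anchor best score falls below ``quality_threshold`` are
    discarded (count reported).  Each surviving region is re-centered on the
    anchor instance center, flipped so the anchor reads on the + strand, and
    every partner PWM is rescanned in the re-centered window; signed
    center-to-center distances (negative = partner upstream of anchor) and
    relative partner strands feed per-strand distance histograms, modal
    distances, and a positional-bias p-value.
    """
    if not 0 < quality_threshold < 1:
        raise ValidationError("quality_threshold must be in (0, 1)")
    anchor_hits = scan_regions(regions, genome, anchor_pwm, window=window)
    passing = [h for h in anchor_hits if h.best_score >= quality_threshold]
    n_discarded = len(anchor_hits) - len(passing)
    if not passing:
        raise ValidationError(
            f"no region has an anchor instance with score >= {quality_threshold}"
        )
    half = window // 2
    # absolute anchor centers (rounded to int) and strands
    centers = []
    strands = []
    for h in passing:
        chrom, center = regions[h.region]
        region_start = int(center) - half
        centers.append((chrom, int(round(region_start + h.center))))
        strands.append(h.strand)
    anchor_minus = np.array([s == "-" for s in strands])
    out: dict[str, MotifArrangement] = {}
    for pwm in partner_pwms:
        hits = scan_regions(centers, genome, pwm, window=window)
        kept_idx = np.array([h.region for h in hits], dtype=int)
        delta = np.array([h.center - half for h in hits])
        pstrand = np.array([h.strand for h in hits])
        aminus = anchor_minus[kept_idx]
        signed = np.where(aminus, -delta, delta)
        rel_strand = np.where(
            aminus, np.where(pstrand == "+", "-", "+"), pstrand
        )
        dist_int = np.rint(signed).astype(int)
        hist = (
            pd.DataFrame({"distance": dist_int, "strand": rel_strand})
            .groupby(["distance", "strand"])
            .size()
            .reset_index(name="count")
            .sort_values(["distance", "strand"])
            .reset_index(drop=True)
        )
        counts = pd.Series(dist_int).value_counts()
        modal = sorted(counts[counts == counts.max()].index.tolist())
        # positional bias of the partner within the re-anchored windows,
        # computed on strand-normalized offsets
        n_off = window - pwm.length + 1
        flip_off = np.array(
            [
                (n_off - 1 - h.offset) if aminus[i] else h.offset
                for i, h in enumerate(hits)
            ]
        )
        norm_hits = [
            RegionHit(h.region, h.best_score, int(flip_off[i]), h.strand, h.center)
            for i, h in enumerate(hits)
        ]
        p_bias = positional_bias(norm_hits, n_offsets=n_off)
        out[pwm.name] = MotifArrangement(
            anchor=anchor_pwm.name,
            partner=pwm.name,
            distances=signed,
            strands=rel_strand,
            histogram=hist,
            modal_distances=[int(d) for d in modal],
            positional_bias_p=p_bias,
            n_regions=len(hits),
            n_discarded=n_discarded,
        )
    return out


# ---------------------------------------------------------------------------
# Reports

def enrichment_report(
    summit_regions: Sequence[tuple[str, int]],
    genome,
    pwm_library: Sequence[PositionWeightModel],
    background_regions: Sequence[tuple[str, int]],
    background_genome=None,
    window: int = DEFAULT_WINDOW,
) -> list[MotifEnrichmentReport]:
    """Global/local/positional enrichment for every motif, ranked by global p.

    The Bonferroni column corrects the global p across the library size.
    """
    if not pwm_library:
        raise ValidationError("empty PWM library")
    if background_genome is None:
        background_genome = genome
    T = len(pwm_library)
    reports = []
    for pwm in pwm_library:
        hits = scan_regions(summit_regions, genome, pwm, window=window)
        bg = scan_regions(background_regions, background_genome, pwm, window=window)
        scores = np.array([h.best_score for h in hits])
        gp = global_enrichment(hits, bg)
        lp = local_enrichment(summit_regions, genome, pwm, window=window)
        pb = positional_bias(hits, n_offsets=window - pwm.length + 1)
        reports.append(
            MotifEnrichmentReport(
                motif=pwm.name,
                mean=float(scores.mean()),
                variance=float(scores.var(ddof=1)) if len(scores) > 1 else 0.0,
                global_p=gp,
                global_p_bonferroni=min(1.0, gp * T),
                local_p=lp,
                positional_bias_p=pb,
                n_regions=len(hits),
                hits=list(hits),
            )
        )
    reports.sort(key=lambda r: (r.global_p, r.motif))
    return reports


def interpret_pair(
    reports: Sequence[MotifEnrichmentReport],
    motif_a: str,
    motif_b: str,
    alpha: float = 0.05,
) -> str:
    """Classify a cobinding TF pair from its motif enrichment.

    Both motifs enriched -> both factors contact DNA ("both bound"); one
    enriched -> the other is tethered without its own site; neither -> no
    direct evidence, possibly a third factor recruits both.
    """
    by_name = {r.motif: r for r in reports}
    for name in (motif_a, motif_b):
        if name not in by_name:
            raise ValidationError(f"motif {name!r} not in the report")
    sig_a = by_name[motif_a].global_p_bonferroni < alpha
    sig_b = by_name[motif_b].global_p_bonferroni < alpha
    if sig_a and sig_b:
        return "both bound"
    if sig_a:
        return f"{motif_b}: tethered (no motif)"
    if sig_b:
        return f"{motif_a}: tethered (no motif)"
    return "no direct evidence; possible third factor"


def report_table(reports: Sequence[MotifEnrichmentReport]) -> pd.DataFrame:
    cols = [
        "motif", "mean", "variance", "global_p", "global_p_bonferroni",
        "local_p", "positional_bias_p", "n_regions",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in reports], columns=cols)
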