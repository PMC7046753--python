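"""Peak and summit I/O, experiment containers, and dataset redundancy filtering.

ChIP-Seq peak callers report enriched regions ("peaks") together with the
position of maximum local enrichment (the "summit"), which is the best proxy
for the protein's actual contact point on DNA.  Everything downstream of this
module works on summit coordinates.  Coordinates are 0-based half-open
throughout (BED convention); a summit is a single 0-based position.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "Experiment",
    "FilterReport",
    "ParseError",
    "ValidationError",
    "read_narrowpeak",
    "write_summits",
    "read_metadata",
    "filter_redundant",
]


class ParseError(ValueError):
    """A peak/metadata file line could not be parsed."""


class ValidationError(ValueError):
    """Input violates a documented precondition."""


KNOWN_FLAGS = frozenset({"stimulated", "tagged", "wildtype"})


@dataclass(frozen=True)
class Peak:
    """One ChIP-Seq peak: half-open interval plus its summit position.

    ``summit`` is absolute (same coordinate system as start/end), with
    ``start <= summit < end``.
    """

    chrom: str
    start: int
    end: int
    summit: int
    signal: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("peak chrom must be non-empty")
        if not self.start < self.end:
            raise ValidationError(f"peak start {self.start} >= end {self.end}")
        if not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"summit {self.summit} outside [{self.start}, {self.end})"
            )


class Experiment:
    """One ChIP-Seq dataset: id, factor name, flags and sorted peak arrays.

    Peaks are stored as parallel numpy arrays sorted by (chrom, summit); the
    sort is applied on construction so every consumer can rely on it.  The
    cobinding statistics only ever need summit positions per chromosome,
    which :meth:`summits` returns as a sorted int64 array.
    """

    def __init__(
        self,
        id: str,
        factor: str,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        summits: Sequence[int],
        signals: Sequence[float] | None = None,
        flags: Iterable[str] = (),
    ) -> None:
        self.id = str(id)
        self.factor = str(factor)
        self.flags = frozenset(flags)
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        summits = np.asarray(summits, dtype=np.int64)
        if signals is None:
            signals = np.zeros(len(chroms), dtype=float)
        signals = np.asarray(signals, dtype=float)
        n = len(chroms)
        if not (len(starts) == len(ends) == len(summits) == len(signals) == n):
            raise ValidationError("peak arrays have unequal lengths")
        if n:
            bad = (starts >= ends) | (summits < starts) | (summits >= ends)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"peak {i} of {self.id}: invalid interval/summit "
                    f"({starts[i]}, {ends[i]}, summit {summits[i]})"
                )
            order = np.lexsort((summits, chroms.astype(str)))
            chroms, starts, ends = chroms[order], starts[order], ends[order]
            summits, signals = summits[order], signals[order]
        self.chroms = chroms
        self.starts = starts
        self.ends = ends
        self.summit_positions = summits
        self.signals = signals
        self._by_chrom: dict[str, np.ndarray] | None = None

    @classmethod
    def from_summits(
        cls,
        id: str,
        factor: str,
        summits: Sequence[int],
        chrom: str | Sequence[str] = "chr1",
        half_width: int = 75,
        flags: Iterable[str] = (),
    ) -> "Experiment":
        """Build an experiment from summit positions alone.

        Peaks become windows of ``2*half_width`` centered on each summit
        (clipped at 0), which is all the downstream statistics need.
        """
        summits = np.asarray(summits, dtype=np.int64)
        if isinstance(chrom, str):
            chroms = np.full(len(summits), chrom, dtype=object)
        else:
            chroms = np.asarray(chrom, dtype=object)
        starts = np.maximum(summits - half_width, 0)
        ends = summits + half_width + 1
        return cls(id, factor, chroms, starts, ends, summits, flags=flags)

    @property
    def n_peaks(self) -> int:
        return len(self.summit_positions)

    @property
    def chrom_names(self) -> list[str]:
        return sorted(set(self.chroms.tolist()))

    def summits(self, chrom: str) -> np.ndarray:
        """Sorted summit positions on one chromosome (empty if absent)."""
        if self._by_chrom is None:
            by: dict[str, np.ndarray] = {}
            for c in self.chrom_names:
                by[c] = self.summit_positions[self.chroms == c]
            self._by_chrom = by
        return self._by_chrom.get(chrom, np.empty(0, dtype=np.int64))

    def peaks(self) -> Iterator[Peak]:
        for i in range(self.n_peaks):
            yield Peak(
                chrom=str(self.chroms[i]),
                start=int(self.starts[i]),
                end=int(self.ends[i]),
                summit=int(self.summit_positions[i]),
                signal=float(self.signals[i]),
            )

    def __len__(self) -> int:
        return self.n_peaks

    def __repr__(self) -> str:
        return (
            f"Experiment(id={self.id!r}, factor={self.factor!r}, "
            f"n_peaks={self.n_peaks}, flags={sorted(self.flags)})"
        )


@dataclass
class FilterReport:
    """Outcome of redundancy filtering: kept ids and (id, reason) discards.

    Reason codes: ``stimulated``, ``tagged_duplicate``, ``small_and_minor``,
    ``redundant_fewer_peaks``, ``ambiguous_overlap``.
    """

    kept: list[str] = field(default_factory=list)
    discarded: list[tuple[str, str]] = field(default_factory=list)
    factors: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": i, "factor": self.factors.get(i, ""), "status": "kept", "reason": ""}
            for i in self.kept
        ] + [
            {"id": i, "factor": self.factors.get(i, ""), "status": "discarded", "reason": r}
            for i, r in self.discarded
        ]
        return pd.DataFrame(rows, columns=["id", "factor", "status", "reason"])

    def write(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: bad {what} {token!r}") from exc


def read_narrowpeak(
    path: str | os.PathLike,
    id: str | None = None,
    factor: str = "",
    flags: Iterable[str] = (),
) -> Experiment:
    """Read an ENCODE narrowPeak (BED6+4) or a 3/4-column BED summit file.

    The format is auto-detected per file from the column count: >=10 columns
    means narrowPeak (column 10 is the summit offset from ``start``; -1 falls
    back to the region midpoint), 3-4 columns means plain BED where a 1-bp
    interval is itself the summit and wider intervals use the midpoint.
    """
    exp_id = id if id is not None else os.path.splitext(os.path.basename(path))[0]
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    summits: list[int] = []
    signals: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            if len(cols) >= 10:
                start = _parse_int(cols[1], "start", lineno)
                end = _parse_int(cols[2], "end", lineno)
                offset = _parse_int(cols[9], "summit offset", lineno)
                try:
                    signal = float(cols[6])
                except ValueError:
                    signal = 0.0
                summit = start + offset if offset >= 0 else (start + end) // 2
            elif 3 <= len(cols) <= 4:
                start = _parse_int(cols[1], "start", lineno)
                end = _parse_int(cols[2], "end", lineno)
                summit = start if end - start == 1 else (start + end) // 2
                signal = 0.0
            else:
                raise ParseError(
                    f"line {lineno}: expected 3-4 or >=10 columns, got {len(cols)}"
                )
            if start >= end:
                raise ParseError(f"line {lineno}: start {start} >= end {end}")
            if not (start <= summit < end):
                raise ValidationError(
                    f"line {lineno}: summit {summit} outside [{start}, {end})"
                )
            chroms.append(cols[0])
            starts.append(start)
            ends.append(end)
            summits.append(summit)
            signals.append(signal)
    return Experiment(exp_id, factor, chroms, starts, ends, summits, signals, flags)


def write_summits(exp: Experiment, path: str | os.PathLike) -> None:
    """Write 1-bp summit records as BED3 ("chrom  summit  summit+1"), sorted.

    Round-trips through :func:`read_narrowpeak` with identical summits.  An
    empty experiment yields an empty file.
    """
    with open(path, "w") as fh:
        for i in range(exp.n_peaks):
            s = int(exp.summit_positions[i])
            fh.write(f"{exp.chroms[i]}\t{s}\t{s + 1}\n")


def read_metadata(path: str | os.PathLike) -> list[dict]:
    """Read the experiment metadata TSV (columns: id, factor, flags).

    ``flags`` is a comma-separated subset of {stimulated, tagged, wildtype};
    the column may be empty or absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("id", "factor"):
        if col not in df.columns:
            raise ParseError(f"metadata file missing required column {col!r}")
    records = []
    for _, row in df.iterrows():
        raw = row.get("flags", "") or ""
        flags = {f.strip() for f in raw.split(",") if f.strip()}
        unknown = flags - KNOWN_FLAGS
        if unknown:
            raise ParseError(f"unknown flags {sorted(unknown)} for id {row['id']!r}")
        records.append({"id": row["id"], "factor": row["factor"], "flags": flags})
    return records


def _overlap_fraction(a: Experiment, b: Experiment, d_s: int) -> float:
    """Summit-overlap fraction k / min(n, m), counted from the smaller set."""
    from .stats import count_cobinding

    small, large = (a, b) if a.n_peaks <= b.n_peaks else (b, a)
    if small.n_peaks == 0:
        return 0.0
    k, _ = count_cobinding(small, large, d_s=d_s)
    return k / small.n_peaks


def filter_redundant(
    experiments: Sequence[Experiment], d_s: int = 150
) -> FilterReport:
    """Resolve redundant experiments per factor.

    Applied in order within each factor group:

    1. drop experiments flagged ``stimulated``;
    2. if both wildtype and tagged experiments remain, drop the tagged ones;
    3. drop any remaining duplicate with fewer than 10,000 peaks that also has
       fewer than half the peaks of every other remaining duplicate;
    4. if more than one remains, keep the largest only when every pairwise
       summit-overlap fraction exceeds 0.66 (fraction = k / min(n, m) with
       summits within ``d_s`` bp); otherwise discard them all.

    Deterministic and order-independent: rule 3 is evaluated simultaneously
    against the pre-removal duplicate set, and the rule-4 winner breaks peak
    count ties by smallest id.
    """
    ids = [e.id for e in experiments]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate experiment ids")
    report = FilterReport(factors={e.id: e.factor for e in experiments})
    by_factor: dict[str, list[Experiment]] = {}
    for e in experiments:
        by_factor.setdefault(e.factor, []).append(e)
    for factor in sorted(by_factor):
        group = sorted(by_factor[factor], key=lambda e: e.id)
        # rule 1: stimulated cells are not considered
        remaining = []
        for e in group:
            if "stimulated" in e.flags:
                report.discarded.append((e.id, "stimulated"))
            else:
                remaining.append(e)
        # rule 2: prefer wild-type over tagged protein when both exist
        if any("wildtype" in e.flags for e in remaining) and any(
            "tagged" in e.flags for e in remaining
        ):
            kept2 = []
            for e in remaining:
                if "tagged" in e.flags:
                    report.discarded.append((e.id, "tagged_duplicate"))
                else:
                    kept2.append(e)
            remaining = kept2
        # rule 3: small and minor duplicates
        if len(remaining) > 1:
            sizes = {e.id: e.n_peaks for e in remaining}
            kept3 = []
            for e in remaining:
                others = [sizes[o.id] for o in remaining if o.id != e.id]
                if e.n_peaks < 10_000 and all(e.n_peaks < s / 2 for s in others):
                    report.discarded.append((e.id, "small_and_minor"))
                else:
                    kept3.append(e)
            remaining = kept3
        # rule 4: concordance among survivors
        if len(remaining) > 1:
            fractions = [
                _overlap_fraction(remaining[i], remaining[j], d_s)
                for i in range(len(remaining))
                for j in range(i + 1, len(remaining))
            ]
            if all(f > 0.66 for f in fractions):
                winner = min(remaining, key=lambda e: (-e.n_peaks, e.id))
                for e in remaining:
                    if e.id == winner.id:
                        report.kept.append(e.id)
                    else:
                        report.discarded.append((e.id, "redundant_fewer_peaks"))
            else:
                for e in remaining:
                    report.discarded.append((e.id, "ambiguous_overlap"))
        elif len(remaining) == 1:
            report.kept.append(remaining[0].id)
    return report
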