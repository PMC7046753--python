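"""Seeded synthetic fixtures: genomes, accessible slots, peaks, and motifs.

The generator emulates the study conditions the statistics assume: the
genome holds ``n_slots`` non-overlapping accessible regions of width 150 bp
separated by 300-bp closed gaps, so two summits in the same slot are always
within 150 bp of each other and summits in different slots never are — the
cobinding count then equals the shared-slot count and the accessible-slot
null applies exactly.  Planted structure is declared as relations:

* ``cobind`` — a fraction of the target experiment's summits are copies of
  source summits jittered by up to +/-30 bp (binding-site centrality);
* ``tether`` — partner experiments place a fraction of their summits on a
  common subset of a base experiment's peaks (a tethered module);
* ``spacing`` — an anchor-motif consensus is written at a fraction of an
  experiment's summits with a partner consensus at a fixed signed
  center-to-center distance and strand, emulating spacing rules between
  binding sites.

Everything is deterministic given the spec's seed; file output uses the
exact formats the package's own readers consume.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .motifs import PositionWeightModel, pwm_from_consensus, write_jaspar
from .peaks import Experiment, ValidationError, write_summits

__all__ = [
    "CobindRelation",
    "TetherRelation",
    "SpacingRelation",
    "ExperimentSpec",
    "FixtureSpec",
    "FixtureBundle",
    "generate",
    "null_replicates",
    "random_slot_experiment",
    "random_sequences",
]

SLOT_WIDTH = 150
SLOT_GAP = 300


@dataclass(frozen=True)
class ExperimentSpec:
    id: str
    factor: str
    n_peaks: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CobindRelation:
    """Target shares ``fraction`` of its summits with source, +/- jitter bp."""

    source: str
    target: str
    fraction: float
    jitter: int = 30


@dataclass(frozen=True)
class TetherRelation:
    """Partners co-place ``fraction`` of the base's peaks (joint module)."""

    base: str
    partners: tuple[str, ...]
    fraction: float
    jitter: int = 30


@dataclass(frozen=True)
class SpacingRelation:
    """Plant anchor+partner consensi at an experiment's summits.

    ``distance`` is the signed center-to-center offset of the partner from
    the anchor; ``strand`` is the partner's strand; ``fraction`` of the
    experiment's summits receive the pair.
    """

    experiment: str
    anchor_motif: str
    partner_motif: str
    distance: int
    strand: str = "+"
    fraction: float = 0.9


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    n_slots: int = 10_000
    slot_width: int = SLOT_WIDTH
    gap: int = SLOT_GAP
    chrom: str = "chr1"
    experiments: tuple[ExperimentSpec, ...] = ()
    cobind: tuple[CobindRelation, ...] = ()
    tether: tuple[TetherRelation, ...] = ()
    spacing: tuple[SpacingRelation, ...] = ()
    motifs: tuple[tuple[str, str], ...] = ()  # (name, consensus)

    @property
    def genome_length(self) -> int:
        return self.gap + self.n_slots * (self.slot_width + self.gap)

    def slot_starts(self) -> np.ndarray:
        return self.gap + np.arange(self.n_slots) * (self.slot_width + self.gap)

    def validate(self) -> None:
        ids = [e.id for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate experiment ids in fixture spec")
        for e in self.experiments:
            if e.n_peaks > self.n_slots:
                raise ValidationError(
                    f"{e.id}: {e.n_peaks} peaks exceed {self.n_slots} slots"
                )
        for rel in self.cobind:
            if not 0 <= rel.fraction <= 1:
                raise ValidationError(f"cobind fraction {rel.fraction} not in [0,1]")
        for rel in self.tether:
            if not 0 <= rel.fraction <= 1:
                raise ValidationError(f"tether fraction {rel.fraction} not in [0,1]")
        for rel in self.spacing:
            if abs(rel.distance) >= self.slot_width:
                raise ValidationError(
                    f"planted distance {rel.distance} must be < {self.slot_width}"
                )


@dataclass
class FixtureBundle:
    """In-memory fixture: genome, slots, experiments, motifs, and truth."""

    spec: FixtureSpec
    genome: dict[str, str]
    slot_starts: np.ndarray
    experiments: dict[str, Experiment]
    pwms: dict[str, PositionWeightModel]
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, outdir: str | os.PathLike) -> None:
        """Write the bundle as FASTA / BED / narrowPeak / JASPAR / TSV files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(outdir / "slots.bed", "w") as fh:
            for s in self.slot_starts:
                fh.write(f"{self.spec.chrom}\t{s}\t{s + self.spec.slot_width}\n")
        meta_rows = []
        for exp_id, exp in self.experiments.items():
            with open(outdir / f"{exp_id}.narrowPeak", "w") as fh:
                for p in exp.peaks():
                    fh.write(
                        f"{p.chrom}\t{p.start}\t{p.end}\t{exp_id}\t0\t.\t"
                        f"{p.signal:g}\t-1\t-1\t{p.summit - p.start}\n"
                    )
            write_summits(exp, outdir / f"{exp_id}.summits.bed")
            meta_rows.append(
                {"id": exp_id, "factor": exp.factor, "flags": ",".join(sorted(exp.flags))}
            )
        pd.DataFrame(meta_rows, columns=["id", "factor", "flags"]).to_csv(
            outdir / "metadata.tsv", sep="\t", index=False
        )
        if self.pwms:
            write_jaspar(list(self.pwms.values()), outdir / "motifs.jaspar")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _summit_in_slot(rng: np.random.Generator, slot_starts: np.ndarray, width: int):
    return slot_starts + rng.integers(0, width, size=len(slot_starts))


def random_slot_experiment(
    rng: np.random.Generator,
    n_peaks: int,
    slot_starts: np.ndarray,
    id: str,
    factor: str = "",
    slot_width: int = SLOT_WIDTH,
    chrom: str = "chr1",
    flags: Sequence[str] = (),
) -> Experiment:
    """One summit in each of ``n_peaks`` uniformly chosen slots (no repeats)."""
    if n_peaks > len(slot_starts):
        raise ValidationError(f"{n_peaks} peaks exceed {len(slot_starts)} slots")
    chosen = rng.choice(len(slot_starts), size=n_peaks, replace=False)
    summits = _summit_in_slot(rng, slot_starts[chosen], slot_width)
    return Experiment.from_summits(id, factor or id, summits, chrom=chrom, flags=flags)


def random_sequences(rng: np.random.Generator, n: int, width: int) -> list[str]:
    """n i.i.d. uniform ACGT sequences of the given width."""
    arr = rng.integers(0, 4, size=(n, width))
    lut = np.array(list("ACGT"))
    return ["".join(row) for row in lut[arr]]


def generate(spec: FixtureSpec, outdir: str | os.PathLike | None = None) -> FixtureBundle:
    """Generate the full fixture bundle; deterministic for a given seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    slot_starts = spec.slot_starts()
    width = spec.slot_width
    truth_rows: list[dict] = []

    # --- peak placement ----------------------------------------------------
    experiments: dict[str, Experiment] = {}
    summit_map: dict[str, np.ndarray] = {}
    # each tether relation on a base gets a disjoint slice of the base's
    # peaks so separately planted modules occupy separate regions
    tether_start: dict[int, int] = {}
    cursor: dict[str, int] = {}
    for ri, rel in enumerate(spec.tether):
        base_spec = next((e for e in spec.experiments if e.id == rel.base), None)
        if base_spec is None:
            raise ValidationError(f"tether base {rel.base!r} not among experiments")
        tether_start[ri] = cursor.get(rel.base, 0)
        cursor[rel.base] = tether_start[ri] + int(round(rel.fraction * base_spec.n_peaks))
    for espec in spec.experiments:
        cob = [r for r in spec.cobind if r.target == espec.id and r.source in summit_map]
        parts: list[np.ndarray] = []
        n_left = espec.n_peaks
        for rel in cob:
            n_shared = int(round(rel.fraction * espec.n_peaks))
            n_shared = min(n_shared, n_left, len(summit_map[rel.source]))
            src = rng.choice(summit_map[rel.source], size=n_shared, replace=False)
            jit = rng.integers(-rel.jitter, rel.jitter + 1, size=n_shared)
            parts.append(np.clip(src + jit, 0, spec.genome_length - 1))
            n_left -= n_shared
            truth_rows.append(
                {
                    "relation": "cobind",
                    "members": f"{rel.source}|{rel.target}",
                    "requested_fraction": rel.fraction,
                    "realized_count": n_shared,
                }
            )
        teth = [
            (ri, r)
            for ri, r in enumerate(spec.tether)
            if espec.id in r.partners and r.base in summit_map
        ]
        for ri, rel in teth:
            base_summits = summit_map[rel.base]
            n_shared = int(round(rel.fraction * len(base_summits)))
            start = min(tether_start[ri], len(base_summits))
            n_shared = min(n_shared, n_left, len(base_summits) - start)
            # same subset for every partner of this relation, disjoint
            # from other relations on the same base
            shared = base_summits[start : start + n_shared]
            jit = rng.integers(-rel.jitter, rel.jitter + 1, size=n_shared)
            parts.append(np.clip(shared + jit, 0, spec.genome_length - 1))
            n_left -= n_shared
            truth_rows.append(
                {
                    "relation": "tether",
                    "members": f"{rel.base}|{espec.id}",
                    "requested_fraction": rel.fraction,
                    "realized_count": n_shared,
                }
            )
        if n_left > 0:
            bg = random_slot_experiment(
                rng, n_left, slot_starts, espec.id, espec.factor,
                slot_width=width, chrom=spec.chrom,
            )
            parts.append(bg.summit_positions)
        summits = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        exp = Experiment.from_summits(
            espec.id, espec.factor, summits, chrom=spec.chrom, flags=espec.flags
        )
        experiments[espec.id] = exp
        summit_map[espec.id] = exp.summit_positions.copy()

    # --- genome and motif planting -----------------------------------------
    pwms: dict[str, PositionWeightModel] = {
        name: pwm_from_consensus(name, cons) for name, cons in spec.motifs
    }
    # the sequence layer is only materialized when something needs it
    want_genome = bool(spec.motifs or spec.spacing) or outdir is not None
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome_arr = (
        lut[rng.integers(0, 4, size=spec.genome_length)]
        if want_genome
        else np.empty(0, dtype=np.uint8)
    )
    comp = str.maketrans("ACGT", "TGCA")
    for rel in spec.spacing:
        for name in (rel.anchor_motif, rel.partner_motif):
            if name not in pwms:
                raise ValidationError(f"spacing relation references unknown motif {name!r}")
        exp = experiments[rel.experiment]
        n_plant = int(round(rel.fraction * exp.n_peaks))
        planted = rng.choice(exp.summit_positions, size=n_plant, replace=False)
        a_cons = pwms[rel.anchor_motif].consensus
        p_cons = pwms[rel.partner_motif].consensus
        if rel.strand == "-":
            p_cons = p_cons.translate(comp)[::-1]
        realized = 0
        for s in planted:
            a_start = int(s) - len(a_cons) // 2
            p_center = int(s) + rel.distance
            p_start = p_center - len(p_cons) // 2
            if a_start < 0 or p_start < 0:
                continue
            if max(a_start + len(a_cons), p_start + len(p_cons)) > spec.genome_length:
                continue
            genome_arr[a_start : a_start + len(a_cons)] = np.frombuffer(
                a_cons.encode(), dtype=np.uint8
            )
            genome_arr[p_start : p_start + len(p_cons)] = np.frombuffer(
                p_cons.encode(), dtype=np.uint8
            )
            realized += 1
        truth_rows.append(
            {
                "relation": "spacing",
                "members": f"{rel.anchor_motif}|{rel.partner_motif}@{rel.experiment}",
                "requested_fraction": rel.fraction,
                "realized_count": realized,
                "distance": rel.distance,
                "strand": rel.strand,
            }
        )
    genome = {spec.chrom: genome_arr.tobytes().decode()} if want_genome else {}

    truth = pd.DataFrame(
        truth_rows,
        columns=["relation", "members", "requested_fraction", "realized_count",
                 "distance", "strand"],
    )
    bundle = FixtureBundle(
        spec=spec,
        genome=genome,
        slot_starts=slot_starts,
        experiments=experiments,
        pwms=pwms,
        truth=truth,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def null_replicates(spec: FixtureSpec, n_reps: int) -> Iterator[FixtureBundle]:
    """Independent replicate bundles with seeds derived from the master seed."""
    if n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {n_reps}")
    for child_seed in derived_seeds(spec.seed, n_reps):
        yield generate(replace(spec, seed=child_seed))


def derived_seeds(master_seed: int, n: int) -> np.ndarray:
    """n reproducible child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return np.array([s.generate_state(1)[0] % (2**31) for s in ss.spawn(n)])
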