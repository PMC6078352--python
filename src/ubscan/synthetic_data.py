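"""Synthetic deep-mutational-scanning data generator.

Emulates a pooled growth competition of a barcoded single-substitution
library of a 76-residue protein: every position from 2 to 76 carries
the 19 non-wild-type amino acids plus a stop codon, each variant tagged
by one or more DNA barcodes.  During the competition each variant's
frequency changes according to its fitness; sequencing a sample of the
pool at successive timepoints yields multinomial barcode counts.

The growth model is exponential with per-generation multiplicative
factor 2^(1+f): wild type (f = 0) doubles every generation and a null
allele (f = -1) does not grow, so the expected slope of
log2(p_v / p_WT) against elapsed generations equals f exactly.  This
makes the log-ratio slope estimator unbiased in expectation.

Condition structure is additive: each named condition shifts the
fitness of all substitutions at a set of target positions by a constant
(negative = sensitizing, positive = alleviating), mirroring the
difference-fitness-map magnitudes (about +-0.25) seen in chemical
perturbation experiments.  The default 17-condition panel reproduces
the design of the ubiquitin perturbation study: a DMSO control, a
sensitizing cluster, a mild/alleviating cluster, a cluster sensitizing
positions 35/46/63, and three idiosyncratic outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .barcode_counts import CountTable, generation_labels
from .fitness import FitnessLandscape
from .variants import (
    RESIDUES,
    STOP,
    YEAST_UBIQUITIN,
    VariantID,
    WT_VARIANT,
    enumerate_substitutions,
    parse_token,
)

_DNA = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class BarcodeMap:
    """Mapping from DNA barcode to library variant.

    All barcodes are unique and of identical length; every variant has
    at least one barcode and each barcode names exactly one variant.
    """

    entries: dict[str, VariantID]
    barcode_length: int
    wt_sequence: str

    def __post_init__(self) -> None:
        for bc in self.entries:
            if len(bc) != self.barcode_length:
                raise ValueError(f"barcode {bc!r} is not length {self.barcode_length}")

    def variants(self) -> list[VariantID]:
        seen: dict[VariantID, None] = {}
        for v in self.entries.values():
            seen.setdefault(v)
        return list(seen)


def write_barcode_map(bmap: BarcodeMap, path: str | Path) -> None:
    """Two-column TSV: barcode, variant token (``K63R``/``K63*``/``WT``)."""
    with open(path, "w") as fh:
        fh.write("barcode\tvariant\n")
        for bc, var in bmap.entries.items():
            fh.write(f"{bc}\t{var.token(bmap.wt_sequence)}\n")


def read_barcode_map(path: str | Path, wt_sequence: str = YEAST_UBIQUITIN) -> BarcodeMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    entries = {
        row.barcode: parse_token(row.variant, wt_sequence) for row in df.itertuples()
    }
    lengths = {len(bc) for bc in entries}
    if len(lengths) != 1:
        raise ValueError("barcodes have inconsistent lengths")
    return BarcodeMap(entries, lengths.pop(), wt_sequence)


def generate_library(
    wt_sequence: str = YEAST_UBIQUITIN,
    barcodes_per_variant: int = 2,
    barcode_length: int = 18,
    seed: int = 0,
    first_position: int = 2,
) -> BarcodeMap:
    """Build a barcoded single-substitution library.

    One entry per (position, residue != WT) pair per barcode replicate,
    plus the same number of barcodes for the wild-type allele.
    Barcodes are drawn uniformly at random without replacement; no
    minimum pairwise distance is enforced.
    """
    if len(wt_sequence) < 2:
        raise ValueError("wild-type sequence must have length >= 2")
    if barcodes_per_variant < 1:
        raise ValueError("barcodes_per_variant must be >= 1")
    variants = list(enumerate_substitutions(wt_sequence, first_position)) + [WT_VARIANT]
    n_needed = len(variants) * barcodes_per_variant
    if 4 ** barcode_length < n_needed:
        raise ValueError(
            f"barcode space exhausted: need {n_needed} barcodes but only "
            f"{4 ** barcode_length} sequences of length {barcode_length} exist"
        )
    rng = np.random.default_rng(seed)
    barcodes: list[str] = []
    seen: set[str] = set()
    while len(barcodes) < n_needed:
        draw = rng.integers(0, 4, size=(n_needed - len(barcodes), barcode_length))
        for row in draw:
            bc = _DNA[row].tobytes().decode()
            if bc not in seen:
                seen.add(bc)
                barcodes.append(bc)
                if len(barcodes) == n_needed:
                    break
    entries: dict[str, VariantID] = {}
    i = 0
    for var in variants:
        for _ in range(barcodes_per_variant):
            entries[barcodes[i]] = var
            i += 1
    return BarcodeMap(entries, barcode_length, wt_sequence)


@dataclass(frozen=True)
class ConditionEffect:
    """Additive fitness shift applied to all substitutions (stops
    excluded) at a set of positions.  Negative = sensitizing,
    positive = alleviating."""

    positions: tuple[int, ...]
    shift: float


@dataclass
class TrueLandscapeConfig:
    """Ground-truth landscape parameters.

    The base (control) landscape draws each substitution's fitness from
    a mixture: with probability ``neutral_fraction`` a near-neutral
    Normal(0, ``neutral_sd``) draw, otherwise a deleterious
    Uniform(-1, 0) draw, clipped to [-1, ``fmax``].  Stops are fixed at
    -1 and wild-type cells at 0 — the anchors of the normalized scale.
    """

    wt_sequence: str = YEAST_UBIQUITIN
    first_position: int = 2
    fmax: float = 0.5
    neutral_fraction: float = 0.7
    neutral_sd: float = 0.03
    condition_effects: Mapping[str, tuple[ConditionEffect, ...]] = field(
        default_factory=dict
    )
    control: str = "DMSO"
    wt_fitness: float = 0.0
    stop_fitness: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wt_fitness != 0.0 or self.stop_fitness != -1.0:
            raise ValueError("scale anchors are fixed: WT fitness 0, stop fitness -1")
        valid = range(self.first_position, len(self.wt_sequence) + 1)
        for name, effects in self.condition_effects.items():
            for eff in effects:
                bad = [p for p in eff.positions if p not in valid]
                if bad:
                    raise ValueError(
                        f"condition {name!r} targets invalid positions {bad}"
                    )


def generate_true_landscape(config: TrueLandscapeConfig) -> dict[str, FitnessLandscape]:
    """Ground-truth fitness landscapes, one per condition.

    The control landscape has no condition effects; every other
    condition equals the control plus its configured additive shifts,
    clipped to [-1, fmax].  Deterministic given ``config.seed``.
    """
    wt = config.wt_sequence
    positions = range(config.first_position, len(wt) + 1)
    rng = np.random.default_rng(config.seed)
    base = pd.DataFrame(
        np.nan, index=pd.RangeIndex(positions.start, positions.stop, name="position"),
        columns=list(RESIDUES),
    )
    for pos in base.index:
        wt_res = wt[pos - 1]
        for res in RESIDUES:
            if res == wt_res:
                base.at[pos, res] = config.wt_fitness
            elif res == STOP:
                base.at[pos, res] = config.stop_fitness
            else:
                if rng.random() < config.neutral_fraction:
                    f = rng.normal(0.0, config.neutral_sd)
                else:
                    f = rng.uniform(-1.0, 0.0)
                base.at[pos, res] = float(np.clip(f, -1.0, config.fmax))

    conditions = dict(config.condition_effects)
    conditions.setdefault(config.control, ())
    out: dict[str, FitnessLandscape] = {}
    for name, effects in conditions.items():
        vals = base.copy()
        for eff in effects:
            for pos in eff.positions:
                wt_res = wt[pos - 1]
                for res in RESIDUES:
                    if res in (wt_res, STOP):
                        continue  # anchors stay fixed
                    vals.at[pos, res] = float(
                        np.clip(vals.at[pos, res] + eff.shift, -1.0, config.fmax)
                    )
        out[name] = FitnessLandscape(
            condition=name, values=vals, wt_sequence=wt, normalized=True
        )
    return out


#: Positions near the hydrophobic patch (8/44/70) and the C-terminal
#: tail — the surface sensitized by the "sensitizing" treatments.
SENSITIZING_POSITIONS = (4, 8, 36, 44, 68, 70, 71, 72, 73, 74, 75, 76)
#: Positions 35/46/63 sensitized (and 58 alleviated) by the salt-stress
#: style cluster.
SALT_CLUSTER_POSITIONS = (35, 46, 63)


def default_condition_panel(seed: int = 0) -> TrueLandscapeConfig:
    """The 17-condition study design: DMSO control, four previously
    characterized treatments, and twelve new chemical perturbations.

    Effect magnitudes are on the +-0.25 scale of difference-fitness
    maps; the three outlier treatments (AmpB, Rapamycin, Tamoxifen)
    carry stronger idiosyncratic profiles.
    """
    sens = ConditionEffect(SENSITIZING_POSITIONS, -0.25)
    mild = ConditionEffect(tuple(range(20, 30)), +0.05)
    salt_down = ConditionEffect(SALT_CLUSTER_POSITIONS, -0.25)
    salt_up = ConditionEffect((58,), +0.15)
    effects: dict[str, tuple[ConditionEffect, ...]] = {
        "DMSO": (),
        # previously characterized sensitizing cluster
        "Caffeine": (sens,),
        "DTT": (sens, ConditionEffect((63,), +0.1)),
        "HU": (sens,),
        # proteasome inhibition alleviates broadly
        "MG132": (ConditionEffect(tuple(range(2, 77)), +0.1),),
        # new members of the sensitizing cluster
        "Cobalt": (sens, ConditionEffect((27, 29, 33), -0.1)),
        "p-FP": (sens,),
        # salt/metal-stress cluster: sensitize 35/46/63, alleviate 58
        "Nickel": (salt_down, salt_up),
        "3-AT": (salt_down, salt_up),
        "CaCl2": (salt_down, salt_up),
        # mild treatments clustering with the control
        "5-FC": (mild,),
        "Tunicamycin": (mild, ConditionEffect((6, 11, 33, 63), +0.1)),
        "Cerulenin": (mild,),
        "Menadione": (),
        # idiosyncratic outliers
        "AmpB": (ConditionEffect(tuple(range(2, 77)), -0.3),),
        "Tamoxifen": (ConditionEffect(tuple(range(2, 77)), +0.25),),
        "Rapamycin": (
            ConditionEffect(tuple(range(2, 40)), -0.3),
            ConditionEffect(tuple(range(40, 77)), +0.2),
        ),
    }
    return TrueLandscapeConfig(condition_effects=effects, seed=seed)


@dataclass
class CompetitionConfig:
    """Growth-competition sampling parameters.

    ``timepoints`` are elapsed generations (first must be 0);
    ``depth`` is the number of reads sampled per timepoint;
    ``initial_frequency_skew`` is the sigma of an optional log-normal
    perturbation of the uniform starting frequencies.
    """

    timepoints: tuple[float, ...] = (0.0, 2.0, 4.0)
    depth: int = 1_000_000
    n_replicates: int = 2
    initial_frequency_skew: float = 0.0
    read_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if len(tp) < 2 or tp[0] != 0 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing and start at 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 <= self.read_error_rate < 0.25):
            raise ValueError("read_error_rate must be in [0, 0.25)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _barcode_fitness(landscape: FitnessLandscape, bmap: BarcodeMap) -> np.ndarray:
    fitness = np.empty(len(bmap.entries))
    for i, var in enumerate(bmap.entries.values()):
        if var.is_wt:
            fitness[i] = 0.0
        else:
            try:
                f = landscape.values.at[var.position, var.residue]
            except KeyError:
                f = np.nan
            if np.isnan(f):
                raise KeyError(
                    f"variant {var.token(bmap.wt_sequence)} missing from landscape "
                    f"{landscape.condition!r}"
                )
            fitness[i] = f
    return fitness


def simulate_competition(
    true_landscape: FitnessLandscape,
    barcode_map: BarcodeMap,
    config: CompetitionConfig,
) -> list[CountTable]:
    """Simulate the pooled competition; one barcode-level CountTable
    per replicate.

    Expected frequencies follow p_v(t) proportional to
    p_v(0) * 2^((1+f_v) t); observed counts at each timepoint are a
    multinomial sample of size ``depth``.  Randomness derives entirely
    from ``config.seed``, with independent sub-streams per replicate
    and timepoint.
    """
    fitness = _barcode_fitness(true_landscape, barcode_map)
    barcodes = list(barcode_map.entries)
    gens = np.asarray(config.timepoints, dtype=float)
    labels = generation_labels(gens)

    tables: list[CountTable] = []
    rep_seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    for rep, rep_ss in enumerate(rep_seeds, start=1):
        children = rep_ss.spawn(len(gens) + 1)
        p0 = np.full(len(barcodes), 1.0 / len(barcodes))
        if config.initial_frequency_skew > 0:
            rng0 = np.random.default_rng(children[0])
            w = np.exp(
                rng0.normal(0.0, config.initial_frequency_skew, size=len(barcodes))
            )
            p0 = w / w.sum()
        counts = pd.DataFrame(
            0, index=pd.Index(barcodes, name="barcode"), columns=labels
        )
        for t, (gen, ss) in enumerate(zip(gens, children[1:])):
            weights = p0 * np.exp2((1.0 + fitness) * gen)
            p = weights / weights.sum()
            rng = np.random.default_rng(ss)
            counts[labels[t]] = rng.multinomial(config.depth, p)
        tables.append(
            CountTable(
                condition=true_landscape.condition,
                replicate=rep,
                generations=gens,
                counts=counts,
                level="barcode",
            )
        )
    return tables


def emit_fastq(
    count_table: CountTable,
    barcode_map: BarcodeMap,
    read_error_rate: float,
    seed: int,
    out_dir: str | Path,
    prefix: str = "reads",
) -> list[Path]:
    """Write one FASTQ file per timepoint.

    Each barcode contributes as many reads as its count; reads are the
    barcode sequence with independent per-base substitution errors at
    ``read_error_rate``, constant Phred+33 quality.  Byte-identical
    output for identical seeds.
    """
    if count_table.level != "barcode":
        raise ValueError("emit_fastq requires a barcode-level table")
    if (count_table.counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    L = barcode_map.barcode_length
    qual = "I" * L
    paths: list[Path] = []
    tp_seeds = np.random.SeedSequence(seed).spawn(len(count_table.timepoint_labels))
    for label, ss in zip(count_table.timepoint_labels, tp_seeds):
        rng = np.random.default_rng(ss)
        path = out_dir / f"{prefix}_{label}.fastq"
        n = 0
        with open(path, "w") as fh:
            for bc, count in count_table.counts[label].items():
                base_arr = np.frombuffer(bc.encode(), dtype="S1")
                for _ in range(int(count)):
                    if read_error_rate > 0:
                        errs = rng.random(L) < read_error_rate
                        if errs.any():
                            read = base_arr.copy()
                            # substitute with a uniformly chosen different base
                            for i in np.nonzero(errs)[0]:
                                choices = _DNA[_DNA != read[i]]
                                read[i] = rng.choice(choices)
                            seq = read.tobytes().decode()
                        else:
                            seq = bc
                    else:
                        seq = bc
                    fh.write(f"@read{n}\n{seq}\n+\n{qual}\n")
                    n += 1
        paths.append(path)
    return paths
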