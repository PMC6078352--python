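"""Barcode counting: from FASTQ reads to count tables.

Each sequencing read carries a DNA barcode identifying one library
member.  Reads are assigned to the unique barcode within a small
Hamming distance of the read's barcode region; ambiguous or unmatched
reads are discarded and tallied.  Barcode-level tables collapse to
variant-level tables by summing the barcodes of each variant.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import BarcodeMap

logger = logging.getLogger(__name__)

_DNA = "ACGT"


@dataclass
class CountTable:
    """Read counts per barcode (or variant) and timepoint.

    ``counts`` rows are barcodes or variant tokens, columns are
    timepoints labelled ``g<generations>``; ``generations`` holds the
    elapsed generations per column.  ``n_discarded`` counts reads that
    could not be assigned, per timepoint.
    """

    condition: str
    replicate: int
    generations: np.ndarray
    counts: pd.DataFrame
    level: str = "barcode"
    n_discarded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=float)
        if self.n_discarded is None:
            self.n_discarded = np.zeros(len(self.generations), dtype=int)
        self.n_discarded = np.asarray(self.n_discarded, dtype=int)
        if self.level not in ("barcode", "variant"):
            raise ValueError(f"level must be 'barcode' or 'variant', got {self.level!r}")
        if len(self.generations) != self.counts.shape[1]:
            raise ValueError("one generations entry per count column required")
        if np.any(np.diff(self.generations) <= 0):
            raise ValueError("generations must be strictly increasing")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def timepoint_labels(self) -> list[str]:
        return list(self.counts.columns)

    def totals(self) -> np.ndarray:
        """Total assigned reads per timepoint."""
        return self.counts.to_numpy().sum(axis=0)


def generation_labels(generations: Sequence[float]) -> list[str]:
    return [f"g{g:g}" for g in generations]


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a count table as TSV with a metadata comment header."""
    path = Path(path)
    gens = ",".join(f"{g:g}" for g in table.generations)
    disc = ",".join(str(int(d)) for d in table.n_discarded)
    header = (
        f"# condition={table.condition}\treplicate={table.replicate}\t"
        f"level={table.level}\tgenerations={gens}\tdiscarded={disc}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        table.counts.rename_axis(table.level).to_csv(fh, sep="\t")


def read_count_table(path: str | Path) -> CountTable:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing metadata header line")
        meta = dict(
            item.split("=", 1) for item in first.lstrip("#").strip().split("\t")
        )
        counts = pd.read_csv(fh, sep="\t", index_col=0)
    generations = np.array([float(g) for g in meta["generations"].split(",")])
    discarded = np.array([int(d) for d in meta["discarded"].split(",")])
    return CountTable(
        condition=meta["condition"],
        replicate=int(meta["replicate"]),
        generations=generations,
        counts=counts,
        level=meta["level"],
        n_discarded=discarded,
    )


def _iter_fastq(path: str | Path):
    """Yield (index, sequence) for each record of a FASTQ file.

    Accepts plain or gzip-compressed files; raises on structurally
    malformed records, naming the record index.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"{path}: malformed FASTQ record at index {idx}")
            seq = seq.strip()
            if len(qual.strip()) != len(seq):
                raise ValueError(f"{path}: malformed FASTQ record at index {idx}")
            yield idx, seq
            idx += 1


def _assign_read(
    seq: str,
    barcode_index: dict[str, str],
    barcode_length: int,
    max_mismatch: int,
    offset: int,
) -> str | None:
    """Assign one read to a barcode, or None if unmatched/ambiguous."""
    region = seq[offset : offset + barcode_length]
    if len(region) < barcode_length:
        return None
    hit = barcode_index.get(region)
    if hit is not None:
        return hit
    if max_mismatch == 0:
        return None
    # enumerate all Hamming-1 neighbours; ambiguity (two distinct hits) discards
    found: str | None = None
    for i, base in enumerate(region):
        prefix, suffix = region[:i], region[i + 1 :]
        for alt in _DNA:
            if alt == base:
                continue
            hit = barcode_index.get(prefix + alt + suffix)
            if hit is not None:
                if found is not None and hit != found:
                    return None
                found = hit
    return found


def extract_and_count(
    fastq_paths: str | Path | Sequence[str | Path],
    barcode_map: "BarcodeMap",
    max_mismatch: int = 1,
    generations: Sequence[float] | None = None,
    condition: str = "unknown",
    replicate: int = 1,
    barcode_offset: int = 0,
) -> CountTable:
    """Count barcode occurrences in FASTQ files (one file per timepoint).

    Each read's barcode region (``barcode_offset`` into the read) is
    matched against the library.  With ``max_mismatch=1`` a read is
    assigned to the unique barcode within Hamming distance 1; reads
    matching no barcode, or equidistant between two, are discarded.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    if generations is None:
        generations = list(range(len(fastq_paths)))
    if len(generations) != len(fastq_paths):
        raise ValueError("one generations entry per FASTQ file required")

    barcodes = list(barcode_map.entries)
    index = {bc: bc for bc in barcodes}
    L = barcode_map.barcode_length
    labels = generation_labels(generations)
    counts = pd.DataFrame(0, index=pd.Index(barcodes, name="barcode"), columns=labels)
    discarded = np.zeros(len(fastq_paths), dtype=int)

    for t, path in enumerate(fastq_paths):
        tally: dict[str, int] = {}
        n_total = 0
        n_disc = 0
        for _, seq in _iter_fastq(path):
            n_total += 1
            hit = _assign_read(seq, index, L, max_mismatch, barcode_offset)
            if hit is None:
                n_disc += 1
            else:
                tally[hit] = tally.get(hit, 0) + 1
        counts[labels[t]] = (
            pd.Series(tally, dtype=float).reindex(barcodes).fillna(0).astype(int).to_numpy()
        )
        discarded[t] = n_disc
        logger.info(
            "%s: %d reads, %d assigned, %d discarded",
            path, n_total, n_total - n_disc, n_disc,
        )

    return CountTable(
        condition=condition,
        replicate=replicate,
        generations=np.asarray(generations, dtype=float),
        counts=counts,
        level="barcode",
        n_discarded=discarded,
    )


def collapse_to_variants(table: CountTable, barcode_map: "BarcodeMap") -> CountTable:
    """Sum barcode-level counts into variant-level counts.

    Every barcode row must be present in the map; totals are conserved.
    """
    if table.level != "barcode":
        raise ValueError("collapse_to_variants requires a barcode-level table")
    unknown = [bc for bc in table.counts.index if bc not in barcode_map.entries]
    if unknown:
        raise KeyError(f"barcode {unknown[0]!r} not in barcode map")
    tokens = [
        barcode_map.entries[bc].token(barcode_map.wt_sequence)
        for bc in table.counts.index
    ]
    collapsed = table.counts.groupby(pd.Index(tokens, name="variant"), sort=True).sum()
    return replace(table, counts=collapsed, level="variant")
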