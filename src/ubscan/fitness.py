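"""Per-variant fitness estimation from pooled growth competitions.

In a pooled competition a variant's frequency changes relative to wild
type at a rate set by its selective effect.  The raw fitness of variant
v is the ordinary least-squares slope of

    log2( (c_v,t + pc) / (c_WT,t + pc) )   against generations t,

where ``pc`` is a pseudocount keeping logarithms finite.  Raw slopes
are then rescaled to the conventional scale on which wild type sits at
0 and the average nonsense (stop) variant at -1, so a fitness of -1
reads as "as deleterious as a premature stop".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .barcode_counts import CountTable
from .variants import RESIDUES, STOP, parse_token, token_position, token_residue

logger = logging.getLogger(__name__)

#: Pseudocount added to every count before forming log-ratios.
DEFAULT_PSEUDOCOUNT = 0.5
#: Variants with fewer reads than this at the first timepoint are masked.
DEFAULT_MIN_T0_COUNT = 10


@dataclass
class FitnessLandscape:
    """Position x residue matrix of fitness values with missing data.

    ``values`` has one row per position (2..L) and one column per
    residue (20 amino acids + stop); missing cells are NaN.  On the
    normalized scale the wild-type residue cell of every position is
    exactly 0 and the mean over non-missing stop cells is -1.
    """

    condition: str
    values: pd.DataFrame
    wt_sequence: str
    normalized: bool = False
    replicate_provenance: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values.index.name = "position"

    @property
    def positions(self) -> np.ndarray:
        return self.values.index.to_numpy()

    def wt_residue(self, position: int) -> str:
        return self.wt_sequence[position - 1]

    def validate(self, atol: float = 1e-9) -> None:
        """Check the normalization anchors and finiteness."""
        vals = self.values.to_numpy()
        if np.isinf(vals).any():
            raise ValueError("landscape contains non-finite values")
        if self.normalized:
            for pos in self.values.index:
                wt_val = self.values.at[pos, self.wt_residue(pos)]
                if not np.isclose(wt_val, 0.0, atol=atol):
                    raise ValueError(f"WT cell at position {pos} is {wt_val}, not 0")
            stops = self.values[STOP].dropna()
            if len(stops) and abs(stops.mean() + 1.0) > atol:
                raise ValueError(f"mean stop fitness {stops.mean()} is not -1")

    def to_series(self, include_wt: bool = False) -> pd.Series:
        """Flatten to a Series indexed by variant token (mutants only
        by default; WT-residue cells are identically 0 and carry no
        information)."""
        out: dict[str, float] = {}
        for pos in self.values.index:
            wt_res = self.wt_residue(pos)
            for res in self.values.columns:
                if res == wt_res and not include_wt:
                    continue
                out[f"{wt_res}{pos}{res}"] = self.values.at[pos, res]
        return pd.Series(out, name=self.condition)


def estimate_raw_fitness(
    table: CountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_t0_count: int = DEFAULT_MIN_T0_COUNT,
) -> pd.Series:
    """Least-squares log2 frequency-ratio slope per variant.

    Requires a variant-level table with a ``WT`` row and at least two
    timepoints.  Returns a Series indexed by variant token; the WT row
    is 0 by construction, and variants failing the minimum-count rule
    at the first timepoint are NaN (masked).
    """
    if table.level != "variant":
        raise ValueError("estimate_raw_fitness requires a variant-level table")
    if len(table.generations) < 2:
        raise ValueError("at least two timepoints are required")
    if "WT" not in table.counts.index:
        raise ValueError("WT row absent from count table")
    wt = table.counts.loc["WT"].to_numpy(dtype=float)
    if (wt == 0).all():
        raise ValueError("WT counts are zero at every timepoint")

    counts = table.counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logratio = np.log2(counts + pseudocount) - np.log2(wt + pseudocount)
    g = table.generations
    gc = g - g.mean()
    # OLS slope against generations, vectorized over variants
    slopes = (logratio * gc).sum(axis=1) / (gc ** 2).sum()

    raw = pd.Series(slopes, index=table.counts.index, name="raw_fitness")
    low = table.counts.iloc[:, 0] < min_t0_count
    raw[low] = np.nan
    raw["WT"] = 0.0
    return raw


def normalize_landscape(
    raw: pd.Series,
    wt_sequence: str,
    condition: str,
    replicate: int | str | None = None,
) -> FitnessLandscape:
    """Rescale raw slopes so that WT = 0 and the mean stop = -1.

    normalized(v) = (raw(v) - raw(WT)) / |mean over stop variants of
    (raw - raw(WT))|.  Requires the WT entry and at least one
    non-missing stop variant with a negative mean (a non-negative stop
    mean indicates a degenerate competition and is an error).
    """
    if "WT" not in raw.index:
        raise ValueError("raw fitness table lacks a WT entry")
    raw_wt = raw["WT"]
    centred = raw - raw_wt
    stop_vals = centred[[t for t in centred.index if t != "WT" and t.endswith(STOP)]].dropna()
    if stop_vals.empty:
        raise ValueError("no non-missing stop variants; cannot anchor the scale")
    mean_stop = stop_vals.mean()
    if mean_stop >= 0:
        raise ValueError(
            f"mean stop raw fitness is {mean_stop:g} (expected negative): degenerate competition"
        )
    normalized = centred / abs(mean_stop)

    n_pos = len(wt_sequence)
    values = pd.DataFrame(
        np.nan, index=pd.RangeIndex(2, n_pos + 1, name="position"), columns=list(RESIDUES)
    )
    for token, val in normalized.items():
        if token == "WT":
            continue
        parse_token(token, wt_sequence)  # validates against the reference
        values.at[token_position(token), token_residue(token)] = val
    for pos in values.index:
        values.at[pos, wt_sequence[pos - 1]] = 0.0

    provenance = (replicate,) if replicate is not None else ()
    return FitnessLandscape(
        condition=condition,
        values=values,
        wt_sequence=wt_sequence,
        normalized=True,
        replicate_provenance=provenance,
    )


def average_replicates(landscapes: Sequence[FitnessLandscape]) -> FitnessLandscape:
    """Cellwise unweighted mean over replicate landscapes.

    A cell missing in any replicate is masked in the output.  A single
    replicate passes through with a logged warning.
    """
    if not landscapes:
        raise ValueError("no landscapes to average")
    first = landscapes[0]
    for other in landscapes[1:]:
        if other.condition != first.condition:
            raise ValueError(
                f"condition mismatch: {other.condition!r} vs {first.condition!r}"
            )
        if other.values.shape != first.values.shape or not other.values.index.equals(
            first.values.index
        ):
            raise ValueError("replicate landscapes have mismatched shapes")
    if len(landscapes) == 1:
        logger.warning(
            "condition %s has a single replicate; averaging is a pass-through",
            first.condition,
        )
    total = landscapes[0].values.copy()
    for other in landscapes[1:]:
        total = total + other.values  # NaN propagates: missing in any replicate masks
    mean = total / len(landscapes)
    provenance = tuple(p for l in landscapes for p in l.replicate_provenance)
    return FitnessLandscape(
        condition=first.condition,
        values=mean,
        wt_sequence=first.wt_sequence,
        normalized=first.normalized,
        replicate_provenance=provenance,
    )


def write_landscape(landscape: FitnessLandscape, path: str | Path) -> None:
    """Write a landscape as TSV (rows positions, columns residues,
    missing = NA) with a JSON metadata sidecar."""
    path = Path(path)
    landscape.values.to_csv(path, sep="\t", na_rep="NA")
    meta = {
        "condition": landscape.condition,
        "wt_sequence": landscape.wt_sequence,
        "normalized": landscape.normalized,
        "replicate_provenance": [str(p) for p in landscape.replicate_provenance],
        "anchors": {"wt_fitness": 0.0, "mean_stop_fitness": -1.0}
        if landscape.normalized
        else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_landscape(path: str | Path) -> FitnessLandscape:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FitnessLandscape(
        condition=meta["condition"],
        values=values,
        wt_sequence=meta["wt_sequence"],
        normalized=meta["normalized"],
        replicate_provenance=tuple(meta["replicate_provenance"]),
    )
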