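"""Difference-fitness maps and position-level sensitivity analysis.

Subtracting the control (DMSO) landscape from a treatment landscape
gives a difference map: negative cells mark condition-specific
sensitization, positive cells increased robustness.  Averaging fitness
over the substitutions at each position, and taking the minimum of
that average across conditions, yields the per-position sensitivity
used to classify residues as tolerant (>= -0.075), intermediate, or
sensitive (<= -0.35).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fitness import FitnessLandscape
from .variants import STOP

#: Class boundaries on the minimum average fitness scale.  Both
#: boundaries are closed toward their named bin: a position at exactly
#: -0.075 is tolerant and one at exactly -0.35 is sensitive.
TOLERANT_THRESHOLD = -0.075
SENSITIVE_THRESHOLD = -0.35

#: Rendering clip range for difference-map heatmaps (applied only at
#: visualization; stored values are never clipped).
DIFFERENCE_RENDER_RANGE = (-0.25, 0.25)


@dataclass
class DifferenceMap:
    """Cellwise treatment-minus-control fitness difference."""

    treatment: str
    control: str
    values: pd.DataFrame
    wt_sequence: str

    def to_series(self) -> pd.Series:
        """Flatten to a mutant-token-indexed Series (substitutions only)."""
        proxy = FitnessLandscape(
            condition=f"{self.treatment}-{self.control}",
            values=self.values,
            wt_sequence=self.wt_sequence,
            normalized=False,
        )
        return proxy.to_series()


@dataclass
class PositionProfile:
    """Per-position average fitness with optional class labels."""

    values: pd.Series
    n_contributing: pd.Series
    condition: str = ""
    labels: pd.Series | None = field(default=None)


def difference_map(
    treatment: FitnessLandscape, control: FitnessLandscape
) -> DifferenceMap:
    """Treatment-minus-control landscape, masking any cell missing in
    either input."""
    for name, l in (("treatment", treatment), ("control", control)):
        if not l.normalized:
            raise ValueError(f"{name} landscape is not normalized")
    if treatment.values.shape != control.values.shape or not treatment.values.index.equals(
        control.values.index
    ):
        raise ValueError("landscapes have mismatched shapes")
    if treatment.wt_sequence != control.wt_sequence:
        raise ValueError("landscapes have different reference sequences")
    values = treatment.values - control.values  # NaN mask propagates (union)
    return DifferenceMap(
        treatment=treatment.condition,
        control=control.condition,
        values=values,
        wt_sequence=treatment.wt_sequence,
    )


def position_average(
    landscape: FitnessLandscape,
    exclude_stops: bool = True,
    exclude_wt: bool = True,
) -> PositionProfile:
    """Unweighted mean fitness over the substitutions at each position.

    Stops and the wild-type cell are excluded by default: the WT cell
    is identically 0 and would dilute every position equally, and stop
    effects reflect truncation rather than substitution.
    """
    cols = list(landscape.values.columns)
    if exclude_stops and STOP in cols:
        cols.remove(STOP)
    sub = landscape.values[cols].copy()
    if exclude_wt:
        for pos in sub.index:
            wt_res = landscape.wt_residue(pos)
            if wt_res in sub.columns:
                sub.at[pos, wt_res] = np.nan
    values = sub.mean(axis=1, skipna=True)
    n = sub.notna().sum(axis=1)
    values[n == 0] = np.nan
    return PositionProfile(
        values=values, n_contributing=n, condition=landscape.condition
    )


def min_across_conditions(profiles: Sequence[PositionProfile]) -> PositionProfile:
    """Per-position minimum of the average fitness across conditions.

    Missing positions are ignored where at least one condition defines
    a value; adding a condition can never increase any position's
    minimum.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    mat = pd.concat([p.values for p in profiles], axis=1)
    values = mat.min(axis=1, skipna=True)
    n = pd.concat([p.n_contributing for p in profiles], axis=1).sum(axis=1)
    names = ",".join(p.condition for p in profiles if p.condition)
    return PositionProfile(values=values, n_contributing=n, condition=f"min({names})")


def classify_positions(
    profile: PositionProfile,
    tolerant_threshold: float = TOLERANT_THRESHOLD,
    sensitive_threshold: float = SENSITIVE_THRESHOLD,
) -> PositionProfile:
    """Bin positions into sensitive / intermediate / tolerant.

    sensitive if value <= sensitive_threshold; tolerant if value >=
    tolerant_threshold; intermediate on the open interval between.
    Masked positions stay unlabeled.
    """
    labels = pd.Series(pd.NA, index=profile.values.index, dtype="object")
    v = profile.values
    labels[v <= sensitive_threshold] = "sensitive"
    labels[v >= tolerant_threshold] = "tolerant"
    labels[(v > sensitive_threshold) & (v < tolerant_threshold)] = "intermediate"
    return PositionProfile(
        values=profile.values,
        n_contributing=profile.n_contributing,
        condition=profile.condition,
        labels=labels,
    )


def write_classification(profile: PositionProfile, path: str | Path) -> None:
    """Three-column TSV: position, min_avg_fitness, class."""
    if profile.labels is None:
        raise ValueError("profile has no labels; run classify_positions first")
    df = pd.DataFrame(
        {
            "position": profile.values.index,
            "min_avg_fitness": profile.values.to_numpy(),
            "class": profile.labels.to_numpy(),
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_difference_map(dmap: DifferenceMap, path: str | Path) -> None:
    dmap.values.to_csv(path, sep="\t", na_rep="NA")


def render_heatmap(
    values: pd.DataFrame,
    path: str | Path,
    clip: tuple[float, float] = DIFFERENCE_RENDER_RANGE,
    title: str = "",
) -> None:
    """Blue-white-red heatmap of a landscape or difference map,
    clipped (for display only) to the given range."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, values.shape[0] / 6), 5))
    im = ax.imshow(
        values.to_numpy().T,
        cmap="bwr_r",
        vmin=clip[0],
        vmax=clip[1],
        aspect="auto",
        interpolation="nearest",
    )
    ax.set_yticks(range(values.shape[1]), values.columns)
    ax.set_xlabel("position")
    ax.set_ylabel("residue")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
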