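"""Ensemble interface ddG aggregation.

Interface binding energetics are predicted on a conformational
ensemble: for each of N models (default 50) of a complex, four
energies are scored — mutant complex, mutant separated partners,
wild-type complex, wild-type separated partners — and the per-model
binding ddG is

    ddG_i = (E_mut_complex,i - E_mut_separated,i)
          - (E_wt_complex,i - E_wt_separated,i).

The final prediction is the unweighted mean of the N per-model scores.
This module consumes pre-computed per-model score tables; it does not
run any molecular modeling.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

#: Conventional ensemble size (one score per backbone model).
DEFAULT_ENSEMBLE_SIZE = 50
#: Mutations with mean ddG above this (energy units) are flagged as
#: destabilizing.  The cutoff is a convention, not a physical constant.
DEFAULT_DESTABILIZING_THRESHOLD = 1.0

ENERGY_COLUMNS = (
    "E_mut_complex",
    "E_mut_separated",
    "E_wt_complex",
    "E_wt_separated",
)


def read_ddg_table(path: str | Path) -> pd.DataFrame:
    """Read a per-model score table: mutation, model_index, and the
    four energy columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("mutation", "model_index") + ENERGY_COLUMNS if c not in df]
    if missing:
        raise ValueError(f"ddG table lacks columns: {missing}")
    return df


def per_model_ddg(table: pd.DataFrame) -> pd.Series:
    """Per-model binding ddG for every row of a score table."""
    for c in ENERGY_COLUMNS:
        if table[c].isna().any():
            raise ValueError(f"missing energies in column {c}")
    return (table["E_mut_complex"] - table["E_mut_separated"]) - (
        table["E_wt_complex"] - table["E_wt_separated"]
    )


def ddg_bind(table: pd.DataFrame) -> pd.Series:
    """Mean binding ddG per mutation over its model ensemble."""
    if len(table) == 0:
        raise ValueError("empty ensemble")
    scores = per_model_ddg(table)
    out = scores.groupby(table["mutation"]).mean()
    out.name = "ddg_bind"
    return out


def destabilizing_profile(
    ddg: pd.Series,
    threshold: float = DEFAULT_DESTABILIZING_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag destabilizing mutations and summarize per position.

    A mutation is destabilizing iff its mean ddG exceeds ``threshold``.
    The per-position summary reports whether all, all but one, or
    fewer of the scored substitutions are flagged, naming the single
    exception where there is one (the pattern of an interface salt
    bridge maintained by exactly one substitution).
    """
    from .variants import token_position, token_residue

    flags = pd.DataFrame(
        {"ddg_bind": ddg, "destabilizing": ddg > threshold}
    ).rename_axis("mutation")
    positions = [token_position(m) for m in flags.index]
    rows = []
    for pos, grp in flags.groupby(pd.Index(positions, name="position")):
        n = len(grp)
        n_flag = int(grp["destabilizing"].sum())
        if n_flag == n:
            pattern, exception = "all", ""
        elif n_flag == n - 1:
            not_flagged = grp.index[~grp["destabilizing"]][0]
            pattern, exception = "all-but-one", token_residue(not_flagged)
        elif n_flag > 0:
            pattern, exception = "some", ""
        else:
            pattern, exception = "none", ""
        rows.append(
            {
                "position": pos,
                "n_scored": n,
                "n_destabilizing": n_flag,
                "pattern": pattern,
                "exception": exception,
            }
        )
    return flags, pd.DataFrame(rows).set_index("position")


def compare_ddg_to_loadings(
    ddg: pd.Series,
    loadings: pd.DataFrame | pd.Series,
    component: int | None = None,
    threshold: float = DEFAULT_DESTABILIZING_THRESHOLD,
) -> dict:
    """Association between predicted destabilization and a principal
    component's loadings over the shared mutations.

    Returns the Spearman rank correlation (energy scales are
    arbitrary, so rank-based association is used) and the 2x2
    contingency of (destabilizing flag x positive loading).
    """
    if isinstance(loadings, pd.DataFrame):
        if component is None:
            raise ValueError("component index required with a loadings matrix")
        loadings = loadings[f"PC{component}"]
    shared = ddg.index.intersection(loadings.index)
    if len(shared) == 0:
        raise ValueError("no shared mutation keys between ddG table and loadings")
    x = ddg.loc[shared]
    y = loadings.loc[shared]
    rho, pvalue = stats.spearmanr(x, y)
    destab = x > threshold
    positive = y > 0
    contingency = pd.crosstab(
        destab.rename("destabilizing"), positive.rename("positive_loading")
    ).reindex(index=[False, True], columns=[False, True], fill_value=0)
    return {
        "n_shared": int(len(shared)),
        "spearman_rho": float(rho),
        "spearman_pvalue": float(pvalue),
        "contingency": contingency,
    }


def generate_synthetic_ensembles(
    true_ddg: dict[str, float],
    n_models: int = DEFAULT_ENSEMBLE_SIZE,
    noise_sd: float = 0.5,
    baseline: float = -100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-model score table with known mean ddG.

    For each mutation the wild-type complex/separated energies sit near
    ``baseline`` with model-to-model variation, and the mutant complex
    energy is offset so that the expected ddG equals the requested
    value.  A fixture generator for testing the aggregation path; not
    a physical model.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for mutation, target in true_ddg.items():
        for i in range(n_models):
            e_wt_sep = baseline + rng.normal(0, noise_sd)
            e_wt_cplx = e_wt_sep - 5.0 + rng.normal(0, noise_sd)
            e_mut_sep = baseline + rng.normal(0, noise_sd)
            e_mut_cplx = e_mut_sep + (e_wt_cplx - e_wt_sep) + target + rng.normal(0, noise_sd)
            rows.append(
                {
                    "mutation": mutation,
                    "model_index": i,
                    "E_mut_complex": e_mut_cplx,
                    "E_mut_separated": e_mut_sep,
                    "E_wt_complex": e_wt_cplx,
                    "E_wt_separated": e_wt_sep,
                }
            )
    return pd.DataFrame(rows)
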