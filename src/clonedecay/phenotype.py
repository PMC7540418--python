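"""Fitness-proxy indices for fish trait tables and their group comparisons.

Indices follow standard fisheries conventions: Clark's condition factor
CC = We / SL^3 (eviscerated weight over cubed standard length), somatic
indices as organ mass over total body mass (heart HI, spleen SSI, liver HSI,
gonad GSI; the denominator is configurable between whole and eviscerated
weight), a vertebrae index VI = vertebra size / SL, the residual of the
log-log length-weight regression (LWR), and absolute / relative fecundity
from oocyte counts.  Growth histories are back-calculated from vertebra
annuli by direct proportion (Dahl–Lea): L_i = SL x r_i / R.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import TestResult, ks_permutation, permutation_test, welch_t

__all__ = [
    "compute_indices",
    "backcalc_growth",
    "compare_groups",
    "INDEX_COLUMNS",
]

INDEX_COLUMNS = ("CC", "LWR", "HI", "SSI", "HSI", "GSI", "VI",
                 "fecundity_abs", "fecundity_rel")


def compute_indices(
    traits: pd.DataFrame,
    denominator: str = "Wt",
    scale_percent: bool = False,
) -> pd.DataFrame:
    """Append condition and fecundity indices to a specimen trait table.

    ``denominator`` selects the body mass used for the somatic indices
    ("Wt" whole or "We" eviscerated).  Rows with non-positive SL or missing
    mass are excluded (flagged in the ``excluded`` return attribute).
    """
    if denominator not in ("Wt", "We"):
        raise ValueError("denominator must be 'Wt' or 'We'")
    df = traits.copy()
    bad = ~(df["SL"] > 0) | df["SL"].isna() | df["Wt"].isna() | ~(df["Wt"] > 0)
    excluded = df.loc[bad, "fish_id"].tolist() if "fish_id" in df else list(df.index[bad])
    df = df.loc[~bad].copy()

    body = df[denominator]
    scale = 100.0 if scale_percent else 1.0
    df["CC"] = df["We"] / df["SL"] ** 3
    coef = np.polyfit(np.log(df["SL"]), np.log(df["Wt"]), 1)
    df["LWR"] = np.log(df["Wt"]) - np.polyval(coef, np.log(df["SL"]))
    df["HI"] = scale * df["heart_g"] / body
    df["SSI"] = scale * df["spleen_g"] / body
    df["HSI"] = scale * df["liver_g"] / body
    df["GSI"] = scale * df["gonad_g"] / body
    df["VI"] = df["vertebra_mm"] / df["SL"]
    if "oocyte_count" in df:
        df["fecundity_abs"] = df["oocyte_count"].astype(float)
        df["fecundity_rel"] = df["oocyte_count"] / df["Wt"]
    df.attrs["excluded"] = excluded
    df.attrs["lw_slope"] = float(coef[0])
    return df


def backcalc_growth(annuli_radii, vertebra_radius: float, SL: float) -> np.ndarray:
    """Back-calculate standard length at each annulus (direct proportion).

    ``annuli_radii`` must be strictly increasing and bounded by the vertebra
    radius; returns lengths monotone in annulus order and <= SL.
    """
    r = np.asarray(annuli_radii, dtype=float)
    if r.size and (np.diff(r) <= 0).any():
        raise ValueError("annuli radii must be strictly increasing")
    if (r < 0).any() or (r > vertebra_radius + 1e-12).any():
        raise ValueError("annuli radii must lie within the vertebra radius")
    if SL <= 0 or vertebra_radius <= 0:
        raise ValueError("SL and vertebra radius must be positive")
    return SL * r / vertebra_radius


def _parse_multi(cell) -> np.ndarray:
    return np.array([float(x) for x in str(cell).split(";") if x != ""], dtype=float)


def compare_groups(
    indices: pd.DataFrame,
    oocytes: pd.DataFrame | None = None,
    group_col: str = "group",
    season_col: str = "season",
    index_cols=None,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Compare condition/fecundity indices between two groups.

    Per index: Welch t over all fish plus a permutation test (abs mean
    difference).  Oocyte diameter distributions are compared per season by
    the permutation Kolmogorov–Smirnov test.  Clutch sizes and survival
    proportions are compared by cluster permutation with the female as the
    nesting unit.  Results are invariant to row order (tables are sorted
    internally) and reproducible given the seed.
    """
    df = indices.sort_values("fish_id").reset_index(drop=True)
    groups = df[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    if index_cols is None:
        index_cols = [c for c in INDEX_COLUMNS if c in df.columns]

    results: dict[str, TestResult] = {}
    labels = df[group_col].to_numpy()
    for k, col in enumerate(index_cols):
        vals = df[col].to_numpy(dtype=float)
        a = vals[labels == groups[0]]
        b = vals[labels == groups[1]]
        results[f"{col}_welch"] = welch_t(a, b)
        results[f"{col}_perm"] = permutation_test(
            vals, labels, n_perm=n_perm, seed=seed + 1000 + k
        )

    if oocytes is not None and len(oocytes):
        oo = oocytes.sort_values(["fish_id", "diameter"]).reset_index(drop=True)
        for k, season in enumerate(sorted(oo[season_col].unique())):
            sub = oo[oo[season_col] == season]
            a = sub.loc[sub[group_col] == groups[0], "diameter"].to_numpy()
            b = sub.loc[sub[group_col] == groups[1], "diameter"].to_numpy()
            if a.size and b.size:
                results[f"oocyte_diam_{season}"] = ks_permutation(
                    a, b, n_perm=n_perm, seed=seed + 2000 + k
                )

    if "clutch_sizes" in df.columns:
        sizes, surv_prop, lab, fish = [], [], [], []
        for _, row in df.iterrows():
            cs = _parse_multi(row["clutch_sizes"])
            sv = _parse_multi(row["survived"]) if "survived" in df.columns else None
            for j, c in enumerate(cs):
                sizes.append(c)
                lab.append(row[group_col])
                fish.append(row["fish_id"])
                if sv is not None:
                    surv_prop.append(sv[j] / c if c > 0 else np.nan)
        sizes = np.array(sizes)
        lab = np.array(lab)
        fish = np.array(fish)
        results["clutch_size"] = permutation_test(
            sizes, lab, n_perm=n_perm, seed=seed + 3000, clusters=fish
        )
        if surv_prop:
            sp = np.array(surv_prop)
            ok = ~np.isnan(sp)
            results["survival"] = permutation_test(
                sp[ok], lab[ok], n_perm=n_perm, seed=seed + 4000, clusters=fish[ok]
            )
    return results
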