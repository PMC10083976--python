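"""Correlated change: slope correlations across traits and informants.

Per-person slopes extracted from the linear growth models (fixed effect +
BLUP deviation) are correlated across traits within a rater, and between
self- and other-reports of the same trait.  Self-other slope agreement can
further be moderated by informant type (family vs friend/roommate), tested
with an OLS interaction model per trait.

Slopes enter correlations untransformed — Pearson r is scale-invariant.
Correlating predicted slopes understates true change correlations because
BLUPs are shrunken, error-contaminated estimates; no disattenuation is
applied, and that caveat travels with the outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from traitchange.core_io import LongPanel
from traitchange.errors import UsageError

MIN_N = 4


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def slope_correlation_matrix(
    slopes: pd.DataFrame, scope: str = "within_rater", rater_role: str = "self"
) -> pd.DataFrame:
    """Correlations of per-person slopes.

    ``scope="within_rater"``: Pearson r for every trait pair within
    ``rater_role`` (tidy rows trait_a, trait_b, r, p, n).
    ``scope="cross_rater"``: per trait, self slope vs other slope across
    persons with both (rows trait, r, p, n).  Cells with fewer than 4 paired
    persons are reported with NaN r/p.
    """
    required = {"person_id", "rater_role", "trait", "slope"}
    if not required.issubset(slopes.columns):
        raise UsageError(f"slope table needs columns {sorted(required)}")
    if slopes.duplicated(["person_id", "rater_role", "trait"]).any():
        raise UsageError("slope table must have one slope per person x rater x trait")
    rows = []
    if scope == "within_rater":
        sub = slopes[slopes["rater_role"] == rater_role]
        wide = sub.pivot(index="person_id", columns="trait", values="slope")
        traits = list(wide.columns)
        for i, a in enumerate(traits):
            for b in traits[i + 1 :]:
                pair = wide[[a, b]].dropna()
                n = len(pair)
                if n < MIN_N:
                    rows.append({"trait_a": a, "trait_b": b, "r": np.nan, "p": np.nan, "n": n})
                    continue
                r, p = _pearson(pair[a].to_numpy(), pair[b].to_numpy())
                rows.append({"trait_a": a, "trait_b": b, "r": r, "p": p, "n": n})
        return pd.DataFrame(rows)
    if scope == "cross_rater":
        roles = set(slopes["rater_role"].unique())
        if not {"self", "other"}.issubset(roles):
            raise UsageError("cross_rater scope needs both self and other slopes")
        for trait, g in slopes.groupby("trait"):
            wide = g.pivot(index="person_id", columns="rater_role", values="slope")
            pair = wide.reindex(columns=["self", "other"]).dropna()
            n = len(pair)
            if n < MIN_N:
                rows.append({"trait": trait, "r": np.nan, "p": np.nan, "n": n})
                continue
            r, p = _pearson(pair["self"].to_numpy(), pair["other"].to_numpy())
            rows.append({"trait": trait, "r": r, "p": p, "n": n})
        return pd.DataFrame(rows)
    raise UsageError(f"unknown scope {scope!r}")


def informant_moderation(
    slopes: pd.DataFrame,
    informant_type: dict[str, str],
    alpha: float = 0.01,
    min_group: int = 5,
) -> pd.DataFrame:
    """Informant-type moderation of self-other slope agreement, per trait.

    Fits ``self_slope ~ other_slope * informant_type`` by OLS for each
    trait.  Informant types are expected to be two levels (e.g. ``family``
    vs ``friend_roommate``).  If only one type is present (or a group is
    smaller than ``min_group``) the main-effects model is returned with
    ``moderation_defined = False``.

    Returns one row per trait with the agreement slope, interaction
    estimate, interaction p, and a significance flag at ``alpha``.
    """
    wide_rows = []
    for trait, g in slopes.groupby("trait"):
        wide = g.pivot(index="person_id", columns="rater_role", values="slope")
        wide = wide.reindex(columns=["self", "other"]).dropna()
        wide["informant_type"] = wide.index.map(informant_type)
        wide = wide.dropna(subset=["informant_type"])
        counts = wide["informant_type"].value_counts()
        defined = len(counts) == 2 and counts.min() >= min_group
        d = wide.rename(columns={"self": "self_slope", "other": "other_slope"})
        if defined:
            fit = smf.ols(
                "self_slope ~ other_slope * C(informant_type)", data=d
            ).fit()
            inter_terms = [t for t in fit.params.index if ":" in t]
            term = inter_terms[0]
            wide_rows.append(
                {
                    "trait": trait,
                    "n": len(d),
                    "moderation_defined": True,
                    "agreement_slope": float(fit.params["other_slope"]),
                    "interaction": float(fit.params[term]),
                    "interaction_p": float(fit.pvalues[term]),
                    "interaction_significant": bool(fit.pvalues[term] < alpha),
                }
            )
        else:
            fit = smf.ols("self_slope ~ other_slope", data=d).fit()
            wide_rows.append(
                {
                    "trait": trait,
                    "n": len(d),
                    "moderation_defined": False,
                    "agreement_slope": float(fit.params["other_slope"]),
                    "interaction": np.nan,
                    "interaction_p": np.nan,
                    "interaction_significant": False,
                }
            )
    return pd.DataFrame(wide_rows)


def baseline_agreement(
    scores: LongPanel, traits: list[str], wave: int = 1
) -> pd.DataFrame:
    """Self-other correlation of observed scores at one wave, per trait.

    The baseline-level analog of the slope-agreement table: levels typically
    agree strongly between self and informant even when change does not.
    """
    df = scores.data
    df = df[(df["wave"] == wave) & (df["variable"].isin(traits))]
    rows = []
    for trait, g in df.groupby("variable"):
        wide = g.pivot_table(
            index="person_id", columns="rater_role", values="value", aggfunc="mean"
        )
        pair = wide.reindex(columns=["self", "other"]).dropna()
        n = len(pair)
        if n < MIN_N:
            rows.append({"trait": trait, "r": np.nan, "p": np.nan, "n": n})
            continue
        r, p = _pearson(pair["self"].to_numpy(), pair["other"].to_numpy())
        rows.append({"trait": trait, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)
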