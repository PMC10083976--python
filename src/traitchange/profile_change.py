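"""Ipsative profile change: Cronbach–Gleser distance decomposition.

A person's trait profile at a wave is the vector of k scale scores (5
domains or 10 aspects, in a fixed order).  Squared Euclidean distances
between two waves' profiles are computed on three score types:

* raw scores (D²) — sensitive to elevation, scatter, and shape;
* deviation scores (D′², profile minus its own mean) — elevation removed;
* standardized scores (D″², deviations divided by the profile SD) — only
  shape remains.

Useful identities (k-1 SD denominator over traits):

* ``D² = D′² + k * (Δ elevation)²``
* ``D″² = 2(k-1)(1 - r_profile)`` where r_profile is the Pearson correlation
  between the two profiles, so ``D″² ∈ [0, 4(k-1)]``.

Per-person change flags compare each distance with the middle interval of a
simulated no-change null (see :mod:`traitchange.null_simulation`); a
distance exactly equal to a cutoff is NOT flagged (strict exceedance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from traitchange.core_io import LongPanel
from traitchange.errors import UsageError

SCORE_TYPES = ("raw", "deviation", "standardized")


def profile_scores(values, score_type: str = "raw") -> np.ndarray:
    """Transform one profile vector to raw, deviation, or standardized form.

    Deviation subtracts the profile mean; standardized further divides by
    the profile SD (k-1 denominator).  A flat profile (SD = 0) has no
    standardized form and raises ``ValueError``; callers exclude and tally
    such person-waves rather than zero them.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise UsageError("a profile must be a 1-d vector of k >= 2 scores")
    if score_type == "raw":
        return x.copy()
    dev = x - x.mean()
    if score_type == "deviation":
        return dev
    if score_type == "standardized":
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("flat profile (SD = 0): standardized scores undefined")
        return dev / sd
    raise UsageError(f"unknown score_type {score_type!r}")


def squared_distance(p_i, p_j) -> float:
    """Squared Euclidean distance sum_k (p_ik - p_jk)^2."""
    a = np.asarray(p_i, dtype=float)
    b = np.asarray(p_j, dtype=float)
    if a.shape != b.shape:
        raise UsageError(f"profile length mismatch: {a.shape} vs {b.shape}")
    d = a - b
    return float(d @ d)


@dataclass
class ProfileDistances:
    """All three distance indices for one person and wave pair."""

    person_id: str
    rater_role: str
    trait_set: str
    wave_pair: tuple[int, int]
    D2_raw: float
    D2_dev: float
    D2_std: float | None  # None when either profile is flat
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float


def distance_triple(
    profile_a, profile_b
) -> tuple[float, float, float | None]:
    """(D², D′², D″²) for two profile vectors; D″² is None if a profile is flat."""
    raw = squared_distance(profile_a, profile_b)
    dev = squared_distance(
        profile_scores(profile_a, "deviation"), profile_scores(profile_b, "deviation")
    )
    try:
        std = squared_distance(
            profile_scores(profile_a, "standardized"),
            profile_scores(profile_b, "standardized"),
        )
    except ValueError:
        std = None
    return raw, dev, std


def compute_profile_distances(
    scores: LongPanel,
    trait_set: list[str] | tuple[str, ...],
    rater_role: str = "self",
    wave_pairs: list[tuple[int, int]] | None = None,
    trait_set_name: str | None = None,
) -> pd.DataFrame:
    """Per-person profile distances for the requested wave pairs.

    ``trait_set`` fixes the variables and their order (identical across
    persons and waves).  Persons lacking a complete profile at either wave
    of a pair are skipped.  Default wave pair is (first, last).

    Returns a tidy DataFrame with one row per person x wave pair and columns
    D2_raw, D2_dev, D2_std (NaN when a profile is flat), plus per-wave
    profile means and SDs as elevation/scatter diagnostics.
    """
    traits = list(trait_set)
    if len(traits) < 2:
        raise UsageError("trait_set needs k >= 2 traits")
    name = trait_set_name or f"traits{len(traits)}"
    df = scores.data
    df = df[(df["rater_role"] == rater_role) & (df["variable"].isin(traits))]
    wide = df.pivot_table(
        index=["person_id", "wave"], columns="variable", values="value", aggfunc="mean"
    )
    missing_traits = [t for t in traits if t not in wide.columns]
    if missing_traits:
        raise UsageError(f"traits absent from panel: {missing_traits}")
    wide = wide[traits]
    waves = sorted(wide.index.get_level_values("wave").unique())
    if wave_pairs is None:
        wave_pairs = [(int(waves[0]), int(waves[-1]))]

    rows = []
    for person, g in wide.groupby(level="person_id"):
        g = g.droplevel("person_id")
        for wa, wb in wave_pairs:
            if wa not in g.index or wb not in g.index:
                continue
            pa, pb = g.loc[wa].to_numpy(), g.loc[wb].to_numpy()
            if np.isnan(pa).any() or np.isnan(pb).any():
                continue
            raw, dev, std = distance_triple(pa, pb)
            rows.append(
                {
                    "person_id": person,
                    "rater_role": rater_role,
                    "trait_set": name,
                    "wave_a": wa,
                    "wave_b": wb,
                    "D2_raw": raw,
                    "D2_dev": dev,
                    "D2_std": np.nan if std is None else std,
                    "mean_a": pa.mean(),
                    "mean_b": pb.mean(),
                    "sd_a": pa.std(ddof=1),
                    "sd_b": pb.std(ddof=1),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "person_id", "rater_role", "trait_set", "wave_a", "wave_b",
            "D2_raw", "D2_dev", "D2_std", "mean_a", "mean_b", "sd_a", "sd_b",
        ],
    )


CHANGE_TYPES = {
    (False, False, False): "no_change",
    (True, False, False): "elevation_only",
    (True, True, False): "elevation_scatter",
    (True, True, True): "elevation_scatter_shape",
}


def classify_change(distances: pd.DataFrame, cutoffs) -> pd.DataFrame:
    """Flag per-person change on each index against null cutoffs.

    A distance is 'changed' iff it lies strictly outside the cutoff
    interval.  Adds boolean columns changed_raw/changed_dev/changed_std
    (changed_std is NA for flat profiles) and a ``change_type`` column with
    the sequential typology: no change / elevation only / elevation+scatter /
    elevation+scatter+shape; combinations outside that nesting are labelled
    ``"other"``.
    """
    from traitchange.null_simulation import NullCutoffs  # cycle guard

    if not isinstance(cutoffs, NullCutoffs):
        raise UsageError("cutoffs must be a NullCutoffs instance")
    if len(distances) and cutoffs.trait_set is not None:
        names = distances["trait_set"].unique()
        if cutoffs.trait_set not in names:
            raise UsageError(
                f"cutoffs built for trait_set {cutoffs.trait_set!r}, "
                f"distances are {list(names)}"
            )
    out = distances.copy()
    lo, hi = cutoffs.interval("raw")
    out["changed_raw"] = (out["D2_raw"] < lo) | (out["D2_raw"] > hi)
    lo, hi = cutoffs.interval("deviation")
    out["changed_dev"] = (out["D2_dev"] < lo) | (out["D2_dev"] > hi)
    lo, hi = cutoffs.interval("standardized")
    std = out["D2_std"]
    out["changed_std"] = ((std < lo) | (std > hi)).where(std.notna())

    def typology(row) -> str:
        key = (
            bool(row["changed_raw"]),
            bool(row["changed_dev"]) if pd.notna(row["changed_dev"]) else False,
            bool(row["changed_std"]) if pd.notna(row["changed_std"]) else False,
        )
        return CHANGE_TYPES.get(key, "other")

    out["change_type"] = out.apply(typology, axis=1) if len(out) else pd.Series(dtype=str)
    return out


def change_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Percent of persons flagged per index, with flat-profile exclusions.

    The standardized-index percentage is computed over persons with a
    defined D″² only; the number excluded for flat profiles is reported.
    """
    rows = []
    for (trait_set, rater, wa, wb), g in classified.groupby(
        ["trait_set", "rater_role", "wave_a", "wave_b"]
    ):
        n = len(g)
        n_std = int(g["changed_std"].notna().sum())
        rows.append(
            {
                "trait_set": trait_set,
                "rater_role": rater,
                "wave_a": wa,
                "wave_b": wb,
                "n": n,
                "pct_changed_raw": 100.0 * g["changed_raw"].mean(),
                "pct_changed_dev": 100.0 * g["changed_dev"].mean(),
                "pct_changed_std": (
                    100.0 * g["changed_std"].dropna().astype(bool).mean()
                    if n_std
                    else np.nan
                ),
                "n_flat_excluded": n - n_std,
            }
        )
    return pd.DataFrame(rows)
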