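"""Data model, readers/writers, scale scoring, and internal consistency.

The central container is :class:`LongPanel`, a tidy long table with one row
per person x rater x wave x variable.  ``variable`` names either raw Likert
items (item-level panel) or scored scales (scale-level panel).  Scoring
follows the Big Five Aspect Scales design: 10 aspect scales of 10 items each
(some reverse-scored), aggregating pairwise into 5 domains of 20 items.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from traitchange.errors import (
    IntegrityError,
    SchemaError,
    UsageError,
    ValidationError,
)

PANEL_COLUMNS = [
    "person_id",
    "informant_id",
    "rater_role",
    "wave",
    "month",
    "variable",
    "value",
]

KEY_COLUMNS = ["item", "scale", "domain", "sign"]

#: Rows identifying one observation.
PANEL_KEY = ["person_id", "informant_id", "rater_role", "wave", "variable"]

RATER_ROLES = ("self", "other")


@dataclass
class LongPanel:
    """Validated long-format panel of observed scores.

    Parameters
    ----------
    data
        DataFrame with columns ``person_id, informant_id, rater_role, wave,
        month, variable, value``.  ``informant_id`` is empty/NaN for self
        rows.
    item_level
        Whether ``variable`` names raw Likert items (values constrained to
        ``[1, likert_max]``) rather than scored scales.
    likert_max
        Top of the Likert response scale (items run 1..likert_max).
    month_tol
        Tolerance for the within-wave constancy of ``month``.
    likert_bounded
        Enforce the [1, likert_max] range on item-level values.  Synthetic
        panels generated without Likert discretization carry continuous
        responses and set this off.
    """

    data: pd.DataFrame
    item_level: bool = True
    likert_max: int = 5
    month_tol: float = 1e-6
    likert_bounded: bool = True

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"panel is missing required columns: {missing}")
        df = self.data.loc[:, PANEL_COLUMNS].copy()
        df["person_id"] = df["person_id"].astype(str)
        df["informant_id"] = df["informant_id"].where(
            df["informant_id"].notna() & (df["informant_id"].astype(str) != ""),
            other=pd.NA,
        )
        df["rater_role"] = df["rater_role"].astype(str)
        bad_role = ~df["rater_role"].isin(RATER_ROLES)
        if bad_role.any():
            rows = df.index[bad_role][:10].tolist()
            raise ValidationError(
                f"rater_role must be one of {RATER_ROLES}; offending rows {rows}"
            )
        df["wave"] = df["wave"].astype(int)
        df["month"] = df["month"].astype(float)
        df["value"] = df["value"].astype(float)
        self._validate(df)
        self.data = df.reset_index(drop=True)

    def _validate(self, df: pd.DataFrame) -> None:
        key = df[PANEL_KEY].astype(str).agg("|".join, axis=1)
        dup = key.duplicated(keep=False)
        if dup.any():
            first = key[dup].iloc[0]
            raise IntegrityError(
                f"duplicate panel key (person_id|informant_id|rater_role|wave|"
                f"variable): {first!r} ({int(dup.sum())} rows involved)"
            )
        if (df["month"] < 0).any():
            rows = df.index[df["month"] < 0][:10].tolist()
            raise ValidationError(f"negative month values at rows {rows}")
        months = df.groupby("wave")["month"]
        spread = months.max() - months.min()
        if (spread > self.month_tol).any():
            w = spread.index[spread > self.month_tol].tolist()
            raise IntegrityError(
                f"month is not constant within wave(s) {w} "
                f"(tolerance {self.month_tol})"
            )
        first_wave = int(df["wave"].min())
        m1 = df.loc[df["wave"] == first_wave, "month"]
        if len(m1) and abs(float(m1.iloc[0])) > self.month_tol:
            raise IntegrityError(
                f"month at the first wave must be 0, got {m1.iloc[0]}"
            )
        if self.item_level and self.likert_bounded:
            vals = df["value"].dropna()
            bad = (vals < 1) | (vals > self.likert_max)
            if bad.any():
                rows = vals.index[bad][:10].tolist()
                raise ValidationError(
                    f"item-level values must lie in [1, {self.likert_max}]; "
                    f"offending rows {rows}"
                )

    # -- convenience accessors -------------------------------------------

    @property
    def waves(self) -> list[int]:
        return sorted(self.data["wave"].unique().tolist())

    @property
    def wave_months(self) -> dict[int, float]:
        return {
            int(w): float(m)
            for w, m in self.data.groupby("wave")["month"].first().items()
        }

    @property
    def variables(self) -> list[str]:
        return sorted(self.data["variable"].unique().tolist())

    def persons(self, rater_role: str | None = None) -> list[str]:
        df = self.data
        if rater_role is not None:
            df = df[df["rater_role"] == rater_role]
        return sorted(df["person_id"].unique().tolist())

    def wave_n(self, rater_role: str = "self") -> dict[int, int]:
        """Persons observed per wave for one rater role."""
        df = self.data[self.data["rater_role"] == rater_role]
        return {
            int(w): int(g["person_id"].nunique())
            for w, g in df.groupby("wave")
        }

    def subset(self, **mask: object) -> "LongPanel":
        df = self.data
        for col, val in mask.items():
            df = df[df[col] == val]
        return LongPanel(
            df.copy(),
            item_level=self.item_level,
            likert_max=self.likert_max,
            month_tol=self.month_tol,
            likert_bounded=self.likert_bounded,
        )

    def to_wide(self) -> pd.DataFrame:
        """One row per person x rater x wave, one column per variable."""
        return (
            self.data.pivot_table(
                index=["person_id", "informant_id", "rater_role", "wave", "month"],
                columns="variable",
                values="value",
                dropna=False,
                observed=True,
            )
            .rename_axis(columns=None)
            .reset_index()
        )

    def equals(self, other: "LongPanel") -> bool:
        a = self.data.sort_values(PANEL_KEY).reset_index(drop=True)
        b = other.data.sort_values(PANEL_KEY).reset_index(drop=True)
        if len(a) != len(b):
            return False
        a_inf = a["informant_id"].astype("string")
        b_inf = b["informant_id"].astype("string")
        return bool(
            (a["person_id"].values == b["person_id"].values).all()
            and (a_inf.fillna("") == b_inf.fillna("")).all()
            and (a["rater_role"].values == b["rater_role"].values).all()
            and (a["wave"].values == b["wave"].values).all()
            and np.allclose(a["month"], b["month"])
            and np.allclose(a["value"], b["value"], equal_nan=True)
            and (a["variable"].values == b["variable"].values).all()
        )


@dataclass
class ScoringKey:
    """Item -> aspect scale -> domain map with reverse-coding signs.

    Each item belongs to exactly one aspect; each aspect to exactly one
    domain; each domain comprises exactly two aspects.  ``sign`` is +1 for
    positively keyed items and -1 for reverse-scored ones.
    """

    table: pd.DataFrame
    likert_max: int = 5
    require_two_aspects: bool = True

    def __post_init__(self) -> None:
        missing = [c for c in KEY_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"scoring key missing columns: {missing}")
        df = self.table.loc[:, KEY_COLUMNS].copy()
        df["sign"] = df["sign"].astype(int)
        if not df["sign"].isin([1, -1]).all():
            raise ValidationError("scoring-key signs must be +1 or -1")
        if df["item"].duplicated().any():
            dups = df.loc[df["item"].duplicated(), "item"].tolist()
            raise IntegrityError(f"items mapped to more than one scale: {dups}")
        per_scale = df.groupby("scale")["domain"].nunique()
        if (per_scale > 1).any():
            bad = per_scale.index[per_scale > 1].tolist()
            raise IntegrityError(f"aspect(s) mapped to multiple domains: {bad}")
        if self.require_two_aspects:
            per_dom = df.groupby("domain")["scale"].nunique()
            if (per_dom != 2).any():
                bad = per_dom[per_dom != 2].to_dict()
                raise IntegrityError(
                    f"each domain must have exactly 2 aspects, got {bad}"
                )
        self.table = df.reset_index(drop=True)

    @property
    def aspects(self) -> list[str]:
        return sorted(self.table["scale"].unique().tolist())

    @property
    def domains(self) -> list[str]:
        return sorted(self.table["domain"].unique().tolist())

    def items_of_aspect(self, aspect: str) -> pd.DataFrame:
        return self.table[self.table["scale"] == aspect]


def read_long_panel(
    path,
    schema: dict[str, str] | None = None,
    item_level: bool = True,
    likert_max: int = 5,
) -> LongPanel:
    """Read a long-format CSV into a validated :class:`LongPanel`.

    ``schema`` optionally maps the canonical column names to the file's
    column names, e.g. ``{"person_id": "pid"}``.
    """
    df = pd.read_csv(path, dtype={"person_id": str, "informant_id": str})
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    return LongPanel(df, item_level=item_level, likert_max=likert_max)


def write_long_panel(panel: LongPanel, path) -> None:
    """Write a panel to UTF-8 CSV with a header row."""
    panel.data.to_csv(path, index=False)


def read_scoring_key(path, likert_max: int = 5) -> ScoringKey:
    """Read a scoring key CSV with columns item,scale,domain,sign."""
    return ScoringKey(pd.read_csv(path), likert_max=likert_max)


def reverse_code(values, likert_max: int = 5):
    """Reverse-score Likert responses: x -> likert_max + 1 - x (involution)."""
    return likert_max + 1 - np.asarray(values, dtype=float)


def score_scales(
    panel: LongPanel,
    key: ScoringKey,
    min_item_coverage: float = 0.8,
) -> LongPanel:
    """Score aspect and domain scales from an item-level panel.

    Reverse-scored items are transformed as ``likert_max + 1 - value``.  An
    aspect score is the mean of its available items; a domain score is the
    mean of its 20 constituent items (equivalent to the item-count-weighted
    mean of its two aspects).  A person-wave scale score is missing unless at
    least ``min_item_coverage`` of the scale's items are observed.

    Scores stay on the 1..likert_max response metric.
    """
    if not panel.item_level:
        raise UsageError("score_scales requires an item-level panel")
    df = panel.data.copy()
    known = set(key.table["item"])
    unknown = sorted(set(df["variable"]) - known)
    if unknown:
        raise KeyError(f"panel contains items absent from the scoring key: {unknown}")

    key_idx = key.table.set_index("item")
    df = df.join(key_idx[["scale", "domain", "sign"]], on="variable")
    rev = df["sign"] == -1
    df.loc[rev, "value"] = reverse_code(df.loc[rev, "value"], key.likert_max)

    n_items_aspect = key.table.groupby("scale")["item"].size()
    n_items_domain = key.table.groupby("domain")["item"].size()

    group_cols = ["person_id", "informant_id", "rater_role", "wave", "month"]
    # a domain that aliases a single aspect name (degenerate one-aspect keys)
    # is scored once, at the aspect level
    aliased = set(n_items_domain.index) & set(n_items_aspect.index)
    frames = []
    for level, n_items in (("scale", n_items_aspect), ("domain", n_items_domain)):
        level_df = df if level == "scale" else df[~df["domain"].isin(aliased)]
        agg = (
            level_df.groupby(group_cols + [level], dropna=False)["value"]
            .agg(score="mean", n_obs="count")
            .reset_index()
            .rename(columns={level: "variable"})
        )
        coverage = agg["n_obs"] / agg["variable"].map(n_items).astype(float)
        agg.loc[(coverage < min_item_coverage) | (agg["n_obs"] == 0), "score"] = np.nan
        agg = agg.rename(columns={"score": "value"}).drop(columns="n_obs")
        frames.append(agg)
    out = pd.concat(frames, ignore_index=True)
    out = out.dropna(subset=["value"])
    return LongPanel(
        out[PANEL_COLUMNS],
        item_level=False,
        likert_max=key.likert_max,
        month_tol=panel.month_tol,
    )


def cronbach_alpha(items) -> float:
    """Cronbach's alpha of a persons x k item matrix.

    ``alpha = k/(k-1) * (1 - sum(item variances) / var(item sum))`` with the
    n-1 variance denominator, computed listwise on complete rows.  Returns
    NaN (with a warning) when the total score has zero variance.
    """
    x = np.asarray(pd.DataFrame(items).dropna(), dtype=float)
    n, k = x.shape
    if k < 2:
        raise ValueError("cronbach_alpha requires at least 2 items")
    if n < 3:
        raise ValueError("cronbach_alpha requires >=3 complete rows")
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        import warnings

        warnings.warn("zero total-score variance: alpha undefined", stacklevel=2)
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


@dataclass
class InformantSelection:
    """Outcome of longitudinal-informant selection."""

    panel: "LongPanel"
    chosen: dict[str, str] = field(default_factory=dict)
    ineligible: list[str] = field(default_factory=list)


def select_longitudinal_informant(
    panel: LongPanel, seed: int, min_waves: int = 2
) -> InformantSelection:
    """Retain one randomly chosen informant per person.

    For each person, keeps all self rows plus the rows of exactly one
    informant drawn uniformly among those observed at >= ``min_waves``
    assessment waves.  Persons whose informants each appear at fewer waves
    keep only self rows and are flagged ineligible.  Reproducible given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    df = panel.data
    others = df[df["rater_role"] == "other"]
    keep = df["rater_role"] == "self"
    chosen: dict[str, str] = {}
    ineligible: list[str] = []
    for person in sorted(df["person_id"].unique()):
        pool = others[others["person_id"] == person]
        if pool.empty:
            continue
        wave_counts = pool.groupby("informant_id", observed=True)["wave"].nunique()
        eligible = sorted(wave_counts.index[wave_counts >= min_waves].tolist())
        if not eligible:
            ineligible.append(person)
            continue
        pick = eligible[int(rng.integers(len(eligible)))]
        chosen[person] = pick
        keep |= (
            (df["person_id"] == person)
            & (df["rater_role"] == "other")
            & (df["informant_id"] == pick)
        )
    out = LongPanel(
        df[keep].copy(),
        item_level=panel.item_level,
        likert_max=panel.likert_max,
        month_tol=panel.month_tol,
        likert_bounded=panel.likert_bounded,
    )
    return InformantSelection(panel=out, chosen=chosen, ineligible=ineligible)
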