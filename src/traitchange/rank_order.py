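"""Rank-order stability: cross-wave correlations and Fisher z tests.

Rank-order stability is the cross-wave Pearson correlation of a trait across
persons.  The increase hypothesis (cumulative continuity) is tested by
comparing the wave-1/2 correlation with the wave-3/4 correlation on the
Fisher z scale.  The default test treats the two correlations as independent
samples; because the wave pairs share persons, a dependence-aware variant
(Steiger-type, using the four-wave correlation matrix) is provided and both
can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from traitchange.core_io import LongPanel
from traitchange.errors import UsageError

MIN_PAIRS = 4


@dataclass
class CrossWaveCorr:
    """Pairwise-complete cross-wave correlation matrix for one trait."""

    trait: str
    rater_role: str
    entries: dict[tuple[int, int], tuple[float, int]]  # (wave_a, wave_b) -> (r, n)
    wide: pd.DataFrame = field(repr=False, default=None)  # person x wave scores

    def r(self, wave_a: int, wave_b: int) -> float:
        return self.entries[self._key(wave_a, wave_b)][0]

    def n(self, wave_a: int, wave_b: int) -> int:
        return self.entries[self._key(wave_a, wave_b)][1]

    def _key(self, a: int, b: int) -> tuple[int, int]:
        key = (min(a, b), max(a, b))
        if key not in self.entries:
            raise UsageError(
                f"wave pair {key} unavailable for {self.trait}/{self.rater_role}"
            )
        return key


def cross_wave_correlations(
    scores: LongPanel, trait: str, rater_role: str = "self"
) -> CrossWaveCorr:
    """Pearson r per wave pair on pairwise-complete persons.

    Cells with fewer than 4 complete pairs are marked unavailable (omitted
    from ``entries``); per-cell n is always recorded.
    """
    df = scores.data
    df = df[(df["variable"] == trait) & (df["rater_role"] == rater_role)]
    if df["wave"].nunique() < 2:
        raise UsageError(f"need >=2 waves for {trait}/{rater_role}")
    wide = df.pivot_table(
        index="person_id", columns="wave", values="value", aggfunc="mean"
    )
    waves = sorted(wide.columns.tolist())
    entries: dict[tuple[int, int], tuple[float, int]] = {}
    for i, wa in enumerate(waves):
        for wb in waves[i + 1 :]:
            pair = wide[[wa, wb]].dropna()
            n = len(pair)
            if n < MIN_PAIRS:
                continue
            r = float(np.corrcoef(pair[wa], pair[wb])[0, 1])
            entries[(int(wa), int(wb))] = (r, n)
    return CrossWaveCorr(trait=trait, rater_role=rater_role, entries=entries, wide=wide)


def fisher_z(r: float) -> float:
    """Fisher z-transformation z = arctanh(r); rejects |r| = 1."""
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError(f"|r| must be < 1 for a finite Fisher z, got r={r}")
    return float(np.arctanh(r))


@dataclass
class StabilityTest:
    """z-difference test of rank-order stability increase."""

    trait: str
    rater_role: str
    early_pair: tuple[int, int]
    late_pair: tuple[int, int]
    r_early: float
    r_late: float
    n_early: int
    n_late: int
    z_diff: float
    p_one_sided: float  # increase hypothesis: r_late > r_early
    p_two_sided: float
    method: str  # "independent" | "dependent"


def _steiger_z(
    corr4: np.ndarray, n: int, jk: tuple[int, int], hm: tuple[int, int]
) -> float:
    """Steiger (1980) Z for two dependent correlations with no shared
    variable, from the 4x4 correlation matrix of the variables involved."""
    j, k = jk
    h, m = hm
    r_jk, r_hm = corr4[j, k], corr4[h, m]
    r_jh, r_jm = corr4[j, h], corr4[j, m]
    r_kh, r_km = corr4[k, h], corr4[k, m]
    # Pearson-Filon covariance term between r_jk and r_hm
    psi = (
        0.5 * r_jk * r_hm * (r_jh**2 + r_jm**2 + r_kh**2 + r_km**2)
        + r_jh * r_km
        + r_jm * r_kh
        - r_jk * (r_jh * r_jm + r_kh * r_km)
        - r_hm * (r_jh * r_kh + r_jm * r_km)
    )
    c = psi / ((1 - r_jk**2) * (1 - r_hm**2))
    z_jk, z_hm = np.arctanh(r_jk), np.arctanh(r_hm)
    return float((z_hm - z_jk) * np.sqrt((n - 3) / (2.0 - 2.0 * c)))


def stability_increase_test(
    corr: CrossWaveCorr,
    early_pair: tuple[int, int] = (1, 2),
    late_pair: tuple[int, int] = (3, 4),
    method: str = "independent",
) -> StabilityTest:
    """Test whether the late-pair correlation exceeds the early-pair one.

    ``method="independent"`` (default) is the simple Fisher z-difference

        z = (z_late - z_early) / sqrt(1/(n_early-3) + 1/(n_late-3)),

    which ignores that the wave pairs share persons.  ``method="dependent"``
    uses a Steiger-type statistic built from the 4-wave correlation matrix on
    persons complete at all four waves.  One- and two-sided normal p-values
    are both reported.
    """
    r_early, n_early = corr.entries[corr._key(*early_pair)]
    r_late, n_late = corr.entries[corr._key(*late_pair)]
    if method == "independent":
        z = (fisher_z(r_late) - fisher_z(r_early)) / np.sqrt(
            1.0 / (n_early - 3) + 1.0 / (n_late - 3)
        )
    elif method == "dependent":
        waves = sorted({*early_pair, *late_pair})
        if len(waves) != 4:
            raise UsageError("dependent method needs four distinct waves")
        complete = corr.wide[waves].dropna()
        n = len(complete)
        if n < MIN_PAIRS:
            raise UsageError("too few persons complete at all four waves")
        corr4 = np.corrcoef(complete.to_numpy(), rowvar=False)
        pos = {w: i for i, w in enumerate(waves)}
        z = _steiger_z(
            corr4,
            n,
            (pos[early_pair[0]], pos[early_pair[1]]),
            (pos[late_pair[0]], pos[late_pair[1]]),
        )
    else:
        raise UsageError(f"unknown method {method!r}")
    return StabilityTest(
        trait=corr.trait,
        rater_role=corr.rater_role,
        early_pair=early_pair,
        late_pair=late_pair,
        r_early=r_early,
        r_late=r_late,
        n_early=n_early,
        n_late=n_late,
        z_diff=float(z),
        p_one_sided=float(stats.norm.sf(z)),
        p_two_sided=float(2 * stats.norm.sf(abs(z))),
        method=method,
    )


def temporal_decay_table(corr: CrossWaveCorr) -> pd.DataFrame:
    """Tidy lag table for decay-curve plots, with the step-ladder diagnostic.

    The step-ladder flag records whether adjacent-wave correlations increase
    over the study: r(3,4) > r(2,3) > r(1,2).  It is NaN when any of those
    cells is unavailable.
    """
    rows = [
        {
            "lag": b - a,
            "wave_a": a,
            "wave_b": b,
            "r": r,
            "n": n,
        }
        for (a, b), (r, n) in sorted(corr.entries.items())
    ]
    table = pd.DataFrame(rows).sort_values(["lag", "wave_a"]).reset_index(drop=True)
    adjacent = [(1, 2), (2, 3), (3, 4)]
    if all(p in corr.entries for p in adjacent):
        r12, r23, r34 = (corr.entries[p][0] for p in adjacent)
        flag: float | bool = bool(r34 > r23 > r12)
    else:
        flag = float("nan")
    table.attrs["step_ladder"] = flag
    return table
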