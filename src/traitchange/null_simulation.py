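"""Simulated no-change null distribution of profile distances.

The null model asks: how large do D², D′², D″² get between two waves when a
person's true profile does not change at all and only measurement error
moves the observed scores?  Each simulated person has

* a single true profile ``T ~ MVN(mu, Sigma_true)`` used at both waves
  (perfect true-score stability), where ``Sigma_true`` equals the observed
  covariance with its diagonal attenuated to ``alpha_k * sigma_k^2``
  (off-diagonal covariances retained; repaired to the nearest PSD matrix if
  attenuation breaks positive semidefiniteness);
* observed wave-w profile ``T + e_w`` with independent error of variance
  ``(1 - alpha_k) * sigma_k^2`` per trait, so each trait's implied retest
  correlation equals its reliability alpha_k and its observed variance
  equals sigma_k^2.

The middle ``interval_mass`` (default 99.9%) of each simulated distance
distribution gives the cutoffs used to flag real profile change.

In the univariate case the null D² is exactly ``2(1-alpha)*sigma^2 * chi2_1``
— used as a closed-form cross-check in the tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from traitchange.core_io import LongPanel, cronbach_alpha
from traitchange.errors import UsageError

DEFAULT_N_SIM = 50_000
DEFAULT_MASS = 0.999


@dataclass
class NullCalibration:
    """Observed moments and reliabilities driving the null simulation."""

    means: np.ndarray
    cov: np.ndarray
    alphas: np.ndarray
    trait_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        self.alphas = np.asarray(self.alphas, dtype=float)
        k = self.means.size
        if self.cov.shape != (k, k):
            raise UsageError("covariance shape must match means")
        if self.alphas.shape != (k,):
            raise UsageError("one alpha per trait required")
        if ((self.alphas <= 0) | (self.alphas > 1)).any():
            raise UsageError("alphas must lie in (0, 1]")
        if np.linalg.eigvalsh((self.cov + self.cov.T) / 2).min() < -1e-8:
            raise UsageError("observed covariance is not positive semidefinite")

    @property
    def k(self) -> int:
        return self.means.size


def calibration_from_panel(
    scores: LongPanel,
    trait_set: list[str],
    item_panel: LongPanel | None = None,
    key=None,
    rater_role: str = "self",
    wave: int = 1,
    alphas: dict[str, float] | None = None,
) -> NullCalibration:
    """Observed-moment calibration from a scored panel at one wave.

    Alphas come either from ``alphas`` directly or from the item-level panel
    and scoring key (Cronbach's alpha per scale at the calibration wave).
    """
    df = scores.data
    df = df[
        (df["rater_role"] == rater_role)
        & (df["wave"] == wave)
        & (df["variable"].isin(trait_set))
    ]
    wide = df.pivot_table(
        index="person_id", columns="variable", values="value", aggfunc="mean"
    )[list(trait_set)].dropna()
    means = wide.mean().to_numpy()
    cov = np.cov(wide.to_numpy(), rowvar=False, ddof=1)
    if alphas is not None:
        a = np.array([alphas[t] for t in trait_set])
    elif item_panel is not None and key is not None:
        a = np.array(
            [
                _scale_alpha(item_panel, key, t, rater_role, wave)
                for t in trait_set
            ]
        )
    else:
        raise UsageError("provide alphas or an item panel with a scoring key")
    return NullCalibration(means=means, cov=cov, alphas=a, trait_names=list(trait_set))


def _scale_alpha(item_panel: LongPanel, key, scale: str, rater_role: str, wave: int) -> float:
    from traitchange.core_io import reverse_code

    items = key.table[
        (key.table["scale"] == scale) | (key.table["domain"] == scale)
    ]
    df = item_panel.data
    df = df[
        (df["rater_role"] == rater_role)
        & (df["wave"] == wave)
        & (df["variable"].isin(items["item"]))
    ].copy()
    signs = items.set_index("item")["sign"]
    rev = df["variable"].map(signs) == -1
    df.loc[rev, "value"] = reverse_code(df.loc[rev, "value"], key.likert_max)
    mat = df.pivot_table(index="person_id", columns="variable", values="value")
    return cronbach_alpha(mat)


@dataclass
class NullCutoffs:
    """Middle-interval bounds of the simulated null per distance index."""

    trait_set: str | None
    intervals: dict[str, tuple[float, float]]  # score_type -> (lower, upper)
    n_sim: int
    interval_mass: float
    seed: int
    calibration: NullCalibration | None = None
    warnings_: list[str] = field(default_factory=list)

    def interval(self, score_type: str) -> tuple[float, float]:
        if score_type not in self.intervals:
            raise UsageError(f"no cutoffs for score_type {score_type!r}")
        return self.intervals[score_type]

    def to_json(self, path) -> None:
        cal = self.calibration
        payload = {
            "trait_set": self.trait_set,
            "intervals": {k: list(v) for k, v in self.intervals.items()},
            "n_sim": self.n_sim,
            "interval_mass": self.interval_mass,
            "seed": self.seed,
            "warnings": self.warnings_,
            "calibration": None
            if cal is None
            else {
                "means": cal.means.tolist(),
                "cov": cal.cov.tolist(),
                "alphas": cal.alphas.tolist(),
                "trait_names": cal.trait_names,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "NullCutoffs":
        with open(path) as fh:
            payload = json.load(fh)
        cal = payload.get("calibration")
        calibration = (
            NullCalibration(
                means=np.array(cal["means"]),
                cov=np.array(cal["cov"]),
                alphas=np.array(cal["alphas"]),
                trait_names=cal.get("trait_names"),
            )
            if cal
            else None
        )
        return cls(
            trait_set=payload.get("trait_set"),
            intervals={k: tuple(v) for k, v in payload["intervals"].items()},
            n_sim=payload["n_sim"],
            interval_mass=payload["interval_mass"],
            seed=payload["seed"],
            calibration=calibration,
            warnings_=payload.get("warnings", []),
        )


def _nearest_psd(mat: np.ndarray) -> tuple[np.ndarray, bool]:
    sym = (mat + mat.T) / 2
    w, q = np.linalg.eigh(sym)
    if w.min() >= 0:
        return sym, False
    w = np.clip(w, 0.0, None)
    return q @ np.diag(w) @ q.T, True


def simulate_null_distances(
    calibration: NullCalibration,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-person (D², D′², D″²) under no true change.

    Returns a DataFrame with columns D2_raw, D2_dev, D2_std of length
    ``n_sim``; D2_std is NaN for (measure-zero) flat simulated profiles.
    Fully vectorized; reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    k = calibration.k
    sigma2 = np.diag(calibration.cov).copy()
    true_cov = calibration.cov.copy()
    np.fill_diagonal(true_cov, calibration.alphas * sigma2)
    true_cov, repaired = _nearest_psd(true_cov)
    warn_list = []
    if repaired:
        msg = "attenuated true-score covariance repaired to nearest PSD"
        warnings.warn(msg, stacklevel=2)
        warn_list.append(msg)
    err_sd = np.sqrt((1.0 - calibration.alphas) * sigma2)

    w, q = np.linalg.eigh(true_cov)
    chol = q @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    T = calibration.means + rng.standard_normal((n_sim, k)) @ chol.T
    obs1 = T + rng.standard_normal((n_sim, k)) * err_sd
    obs2 = T + rng.standard_normal((n_sim, k)) * err_sd

    d_raw = ((obs1 - obs2) ** 2).sum(axis=1)
    dev1 = obs1 - obs1.mean(axis=1, keepdims=True)
    dev2 = obs2 - obs2.mean(axis=1, keepdims=True)
    d_dev = ((dev1 - dev2) ** 2).sum(axis=1)
    if k >= 2:
        sd1 = obs1.std(axis=1, ddof=1, keepdims=True)
        sd2 = obs2.std(axis=1, ddof=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            std1 = np.where(sd1 > 0, dev1 / sd1, np.nan)
            std2 = np.where(sd2 > 0, dev2 / sd2, np.nan)
        d_std = ((std1 - std2) ** 2).sum(axis=1)
    else:
        d_std = np.full(n_sim, np.nan)
    out = pd.DataFrame({"D2_raw": d_raw, "D2_dev": d_dev, "D2_std": d_std})
    out.attrs["warnings"] = warn_list
    return out


def derive_cutoffs(
    null_distances: pd.DataFrame,
    interval_mass: float = DEFAULT_MASS,
    trait_set: str | None = None,
    seed: int = 0,
    calibration: NullCalibration | None = None,
) -> NullCutoffs:
    """Empirical middle-interval quantiles of the simulated null.

    Bounds sit at quantiles ``(1-mass)/2`` and ``1-(1-mass)/2`` per index.
    Warns (in the cutoffs metadata) when ``n_sim`` leaves fewer than ~10
    observations beyond each bound.
    """
    if not 0.0 < interval_mass < 1.0:
        raise UsageError("interval_mass must lie in (0, 1)")
    n_sim = len(null_distances)
    warn_list = list(null_distances.attrs.get("warnings", []))
    if n_sim < 20.0 / (1.0 - interval_mass):
        msg = (
            f"n_sim={n_sim} gives thin tails for interval_mass={interval_mass}; "
            f"recommend n_sim >= {int(np.ceil(20 / (1 - interval_mass)))}"
        )
        warnings.warn(msg, stacklevel=2)
        warn_list.append(msg)
    lo_q, hi_q = (1.0 - interval_mass) / 2.0, 1.0 - (1.0 - interval_mass) / 2.0
    intervals = {}
    for col, key in (
        ("D2_raw", "raw"),
        ("D2_dev", "deviation"),
        ("D2_std", "standardized"),
    ):
        vals = null_distances[col].dropna().to_numpy()
        if vals.size == 0:
            continue
        intervals[key] = (float(np.quantile(vals, lo_q)), float(np.quantile(vals, hi_q)))
    return NullCutoffs(
        trait_set=trait_set,
        intervals=intervals,
        n_sim=n_sim,
        interval_mass=interval_mass,
        seed=seed,
        calibration=calibration,
        warnings_=warn_list,
    )


def simulate_null_cutoffs(
    calibration: NullCalibration,
    trait_set: str | None = None,
    n_sim: int = DEFAULT_N_SIM,
    interval_mass: float = DEFAULT_MASS,
    seed: int = 0,
) -> NullCutoffs:
    """Convenience wrapper: simulate the null then derive cutoffs."""
    dists = simulate_null_distances(calibration, n_sim=n_sim, seed=seed)
    return derive_cutoffs(
        dists,
        interval_mass=interval_mass,
        trait_set=trait_set,
        seed=seed,
        calibration=calibration,
    )
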