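"""Synthetic multi-informant longitudinal panel generator.

Emulates the design of a four-wave college personality panel: 259 persons at
baseline with monotone attrition to 196/191/150, assessments at months
0/6/13/19, ten aspect scales of ten Likert items each (some reverse-scored)
aggregating pairwise into five domains, and informant reports whose latent
levels and slopes agree with self-reports to a configurable degree.

The generative model, per person i, trait k, rater r, month t::

    level_ikr(t) = mean_k + u_ikr + (beta_k + v_ikr) * t + q_k * t**2
    scale score  = level + residual noise
    item_j       = scale score + item noise  (variance solved from alpha)

Intercepts ``u`` and slopes ``v`` are multivariate normal across traits with
a configurable trait correlation matrix, within-trait intercept-slope
correlation, and self-other correlations for both levels and slopes.  The
latent truth table (per-person intercepts and slopes) is returned alongside
the observed panel for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from traitchange.core_io import PANEL_COLUMNS, LongPanel, ScoringKey
from traitchange.errors import ConfigError

#: BFAS-style design: domain -> its two aspects.
BFAS_DOMAINS: dict[str, tuple[str, str]] = {
    "Agreeableness": ("Compassion", "Politeness"),
    "Conscientiousness": ("Industriousness", "Orderliness"),
    "Extraversion": ("Assertiveness", "Enthusiasm"),
    "Neuroticism": ("Volatility", "Withdrawal"),
    "OpennessIntellect": ("Intellect", "Openness"),
}


@dataclass
class TraitSpec:
    """Generating parameters for one aspect scale."""

    name: str
    domain: str = ""
    n_items: int = 10
    target_alpha: float = 0.80
    mean: float = 3.4
    intercept_sd: float = 0.45
    fixed_slope: float = 0.002  # score units / month
    quad_coef: float = 0.0  # score units / month^2
    slope_sd: float = 0.015
    residual_sd: float = 0.15


@dataclass
class GeneratorConfig:
    """Full panel-generator configuration.

    ``retention`` may be absolute per-wave counts (non-increasing) or
    per-wave retention probabilities in (0, 1]; attrition is monotone either
    way.  ``self_other_true_corr`` controls agreement of latent levels
    between self and informant reports, ``self_other_slope_corr`` agreement
    of latent slopes.
    """

    traits: list[TraitSpec]
    n_persons: int = 259
    wave_months: tuple[float, ...] = (0.0, 6.0, 13.0, 19.0)
    retention: tuple[float, ...] = (259, 196, 191, 150)
    trait_correlation: np.ndarray | None = None
    intercept_slope_corr: float = -0.2
    self_other_true_corr: float = 0.5
    self_other_slope_corr: float = 0.3
    n_informants: int = 1
    informant_wave_prob: float = 1.0
    likert_discretize: bool = True
    likert_max: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.retention) != len(self.wave_months):
            raise ConfigError("retention and wave_months must align per wave")
        r = np.asarray(self.retention, dtype=float)
        if (r <= 1.0).all():
            counts = np.round(r * self.n_persons).astype(int)
        else:
            counts = r.astype(int)
        if (np.diff(counts) > 0).any():
            raise ConfigError("retention must be non-increasing across waves")
        if counts[0] > self.n_persons:
            raise ConfigError("wave-1 retention exceeds n_persons")
        self.retention_counts: tuple[int, ...] = tuple(int(c) for c in counts)
        for t in self.traits:
            if not (0.0 < t.target_alpha <= 1.0):
                raise ConfigError(
                    f"target_alpha for {t.name} must be in (0, 1]; any value in "
                    f"that range is attainable for n_items >= 2"
                )
            if t.n_items < 1:
                raise ConfigError(f"{t.name}: n_items must be >= 1")
            if min(t.intercept_sd, t.slope_sd, t.residual_sd) < 0:
                raise ConfigError(f"{t.name}: SDs must be non-negative")
        k = len(self.traits)
        if self.trait_correlation is None:
            self.trait_correlation = _default_trait_correlation(self.traits)
        tc = np.asarray(self.trait_correlation, dtype=float)
        if tc.shape != (k, k):
            raise ConfigError(f"trait_correlation must be {k}x{k}")
        if not np.allclose(tc, tc.T):
            raise ConfigError("trait_correlation must be symmetric")
        if np.linalg.eigvalsh(tc).min() < -1e-10:
            raise ConfigError("trait_correlation is not positive semidefinite")
        self.trait_correlation = tc
        for name, val in [
            ("intercept_slope_corr", self.intercept_slope_corr),
            ("self_other_slope_corr", self.self_other_slope_corr),
        ]:
            if not -1.0 <= val <= 1.0:
                raise ConfigError(f"{name} must lie in [-1, 1]")
        if not 0.0 <= self.self_other_true_corr <= 1.0:
            raise ConfigError("self_other_true_corr must lie in [0, 1]")

    def with_overrides(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def _default_trait_correlation(traits: list[TraitSpec]) -> np.ndarray:
    """Within-domain aspect correlation 0.5, cross-domain 0.15."""
    k = len(traits)
    tc = np.full((k, k), 0.15)
    for i in range(k):
        for j in range(k):
            if traits[i].domain and traits[i].domain == traits[j].domain:
                tc[i, j] = 0.5
    np.fill_diagonal(tc, 1.0)
    return tc


def default_bfas_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Study-design default: 259 persons, retention 259/196/191/150, waves at
    months 0/6/13/19, ten aspects with alphas spread over 0.74-0.88."""
    alphas = [0.84, 0.78, 0.82, 0.86, 0.88, 0.85, 0.87, 0.80, 0.74, 0.76]
    means = [3.9, 3.6, 3.5, 3.3, 3.4, 3.7, 2.8, 2.9, 3.8, 3.6]
    traits = []
    i = 0
    for domain, (a1, a2) in BFAS_DOMAINS.items():
        for aspect in (a1, a2):
            traits.append(
                TraitSpec(
                    name=aspect,
                    domain=domain,
                    target_alpha=alphas[i],
                    mean=means[i],
                )
            )
            i += 1
    return GeneratorConfig(traits=traits, seed=seed, **overrides)


def make_scoring_key(config: GeneratorConfig, n_reversed: int = 4) -> ScoringKey:
    """Scoring key matching the generated item names; the last ``n_reversed``
    items of each aspect are reverse-scored."""
    rows = []
    for t in config.traits:
        for j in range(1, t.n_items + 1):
            rows.append(
                {
                    "item": f"{t.name}_{j:02d}",
                    "scale": t.name,
                    "domain": t.domain or t.name,
                    "sign": -1 if j > t.n_items - n_reversed else 1,
                }
            )
    df = pd.DataFrame(rows)
    two_aspects = df.groupby("domain")["scale"].nunique().eq(2).all()
    return ScoringKey(df, likert_max=config.likert_max, require_two_aspects=bool(two_aspects))


def _item_noise_sd(t: TraitSpec) -> float:
    """Item-noise SD solving Cronbach's alpha for parallel items.

    With item_j = y + e_j, e_j iid N(0, s^2), and between-person variance of
    the common part V = intercept_sd^2 + residual_sd^2 (baseline), alpha of
    the k-item scale is kV / (kV + s^2); solve for s.
    """
    V = t.intercept_sd**2 + t.residual_sd**2
    if t.target_alpha >= 1.0:
        return 0.0
    if V <= 0:
        raise ConfigError(
            f"{t.name}: target_alpha < 1 requires positive between-person "
            f"variance (intercept_sd or residual_sd > 0)"
        )
    s2 = t.n_items * V * (1.0 - t.target_alpha) / t.target_alpha
    return float(np.sqrt(s2))


def _draw_latents(config: GeneratorConfig, rng: np.random.Generator):
    """Draw per-person latent intercept/slope deviations for self and each
    informant; returns dict rater_label -> (u, v) arrays of shape (n, k)."""
    n, k = config.n_persons, len(config.traits)
    tc = config.trait_correlation
    sd_i = np.array([t.intercept_sd for t in config.traits])
    sd_s = np.array([t.slope_sd for t in config.traits])
    rho = config.intercept_slope_corr

    # joint (intercept, slope) in standardized units: 2k x 2k correlation
    joint = np.block([[tc, rho * tc], [rho * tc, tc]])
    w, q = np.linalg.eigh(joint)
    chol = q @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    def draw_pair() -> tuple[np.ndarray, np.ndarray]:
        z = rng.standard_normal((n, 2 * k)) @ chol.T
        return z[:, :k], z[:, k:]

    z_int_self, z_slo_self = draw_pair()
    out = {"self": (z_int_self * sd_i, z_slo_self * sd_s)}
    rho_t, rho_s = config.self_other_true_corr, config.self_other_slope_corr
    for m in range(1, config.n_informants + 1):
        zi_w, zs_w = draw_pair()
        zi = rho_t * z_int_self + np.sqrt(1 - rho_t**2) * zi_w
        zs = rho_s * z_slo_self + np.sqrt(1 - rho_s**2) * zs_w
        out[f"other{m}"] = (zi * sd_i, zs * sd_s)
    return out


def _assign_last_wave(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Monotone attrition: person i observed at waves 1..last_wave[i];
    per-wave counts match retention exactly."""
    counts = list(config.retention_counts)
    n = config.n_persons
    n_waves = len(counts)
    last = np.zeros(n, dtype=int)
    order = rng.permutation(n)
    in_wave1 = order[: counts[0]]
    last[in_wave1] = 1
    current = in_wave1
    for w in range(1, n_waves):
        current = rng.permutation(current)[: counts[w]]
        last[current] = w + 1
    return last


def generate_panel(
    config: GeneratorConfig,
) -> tuple[LongPanel, pd.DataFrame]:
    """Generate an item-level observed panel plus the latent-truth table.

    Returns
    -------
    panel : LongPanel
        Item-level observations (values on the 1..likert_max grid when
        ``likert_discretize`` is on, raw continuous otherwise).
    truth : DataFrame
        One row per person x rater x trait with the latent ``intercept``
        (deviation from the trait mean) and ``slope`` (total individual
        slope, fixed + deviation), for parameter-recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    k = len(config.traits)
    n = config.n_persons
    months = np.asarray(config.wave_months, dtype=float)
    n_waves = len(months)
    person_ids = np.array([f"P{i + 1:04d}" for i in range(n)])

    latents = _draw_latents(config, rng)
    last_wave = _assign_last_wave(config, rng)

    means = np.array([t.mean for t in config.traits])
    betas = np.array([t.fixed_slope for t in config.traits])
    quads = np.array([t.quad_coef for t in config.traits])
    res_sd = np.array([t.residual_sd for t in config.traits])
    item_sd = np.array([_item_noise_sd(t) for t in config.traits])
    key = make_scoring_key(config)
    key_by_trait = {
        t.name: key.items_of_aspect(t.name).reset_index(drop=True)
        for t in config.traits
    }

    frames: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []
    for rater_label, (u, v) in latents.items():
        is_self = rater_label == "self"
        role = "self" if is_self else "other"
        # informant ids are person-specific (P0001-I1, ...)
        informant_ids = (
            None
            if is_self
            else np.char.add(person_ids, f"-I{rater_label.removeprefix('other')}")
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "person_id": np.repeat(person_ids, k),
                    "rater_role": role,
                    "informant_id": None
                    if is_self
                    else np.repeat(informant_ids, k),
                    "trait": np.tile([t.name for t in config.traits], n),
                    "intercept": u.ravel(),
                    "slope": (betas[None, :] + v).ravel(),
                }
            )
        )
        for w in range(n_waves):
            present = last_wave >= (w + 1)
            if not is_self and config.informant_wave_prob < 1.0:
                present = present & (
                    rng.random(n) < config.informant_wave_prob
                )
            idx = np.flatnonzero(present)
            if idx.size == 0:
                continue
            t_m = months[w]
            # latent scale level, then observed scale score per trait
            level = (
                means[None, :]
                + u[idx]
                + (betas[None, :] + v[idx]) * t_m
                + quads[None, :] * t_m**2
            )
            score = level + rng.standard_normal(level.shape) * res_sd[None, :]
            for j, trait in enumerate(config.traits):
                items = key_by_trait[trait.name]
                n_it = len(items)
                resp = (
                    score[:, j][:, None]
                    + rng.standard_normal((idx.size, n_it)) * item_sd[j]
                )
                # reverse-scored items are stored on the reversed metric so
                # that scoring recovers the latent response
                signs = items["sign"].to_numpy()
                stored = np.where(
                    signs[None, :] == -1, config.likert_max + 1 - resp, resp
                )
                if config.likert_discretize:
                    stored = np.clip(
                        np.round(stored), 1, config.likert_max
                    )
                frames.append(
                    pd.DataFrame(
                        {
                            "person_id": np.repeat(person_ids[idx], n_it),
                            "informant_id": None
                            if is_self
                            else np.repeat(informant_ids[idx], n_it),
                            "rater_role": role,
                            "wave": w + 1,
                            "month": t_m,
                            "variable": np.tile(items["item"].to_numpy(), idx.size),
                            "value": stored.ravel(),
                        }
                    )
                )
    data = pd.concat(frames, ignore_index=True)
    panel = LongPanel(
        data[PANEL_COLUMNS],
        item_level=True,
        likert_max=config.likert_max,
        likert_bounded=config.likert_discretize,
    )
    truth = pd.concat(truth_rows, ignore_index=True)
    return panel, truth


def five_domain_profile_config(
    seed: int = 0, n_persons: int = 500, **overrides
) -> GeneratorConfig:
    """Five domain-level traits for profile-change calibration studies.

    Reliabilities span 0.75-0.85 and the trait means are spread across the
    Likert range, as Big Five domain norms are; the mean spread is what gives
    every person a non-flat normative profile and hence a usable
    standardized-distance null.
    """
    alphas = [0.75, 0.78, 0.80, 0.82, 0.85]
    means = [3.9, 3.5, 3.4, 2.85, 3.7]
    traits = [
        TraitSpec(name=name, domain=name, target_alpha=a, mean=m)
        for name, a, m in zip(BFAS_DOMAINS, alphas, means)
    ]
    overrides.setdefault("wave_months", (0.0,))
    overrides.setdefault("retention", (1.0,))
    overrides.setdefault("n_informants", 0)
    return GeneratorConfig(traits=traits, n_persons=n_persons, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# profile-change fixture cohorts
# ---------------------------------------------------------------------------

CHANGE_LABELS = ("none", "elevation_only", "elevation_scatter", "elevation_scatter_shape")


@dataclass
class ChangeSpec:
    """Assignment of profile-change types and their effect magnitudes.

    ``counts`` gives the number of persons per change label.  Elevation adds
    ``elevation_shift`` to every trait at the second wave; scatter multiplies
    deviations from the person-profile mean by ``scatter_factor``; shape
    either sign-flips (``"flip"``) or cyclically permutes (``"permute"``) the
    deviations.
    """

    counts: dict[str, int] = field(
        default_factory=lambda: {label: 50 for label in CHANGE_LABELS}
    )
    elevation_shift: float = 1.0
    scatter_factor: float = 4.0
    shape_mode: str = "flip"

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(CHANGE_LABELS)
        if unknown:
            raise ConfigError(f"unknown change labels: {sorted(unknown)}")
        if self.shape_mode not in ("flip", "permute"):
            raise ConfigError("shape_mode must be 'flip' or 'permute'")


def _apply_change(
    profile: np.ndarray, label: str, spec: ChangeSpec
) -> np.ndarray:
    m = profile.mean()
    dev = profile - m
    if label == "none":
        return profile.copy()
    if label == "elevation_only":
        return profile + spec.elevation_shift
    if label == "elevation_scatter":
        return m + spec.elevation_shift + spec.scatter_factor * dev
    # elevation + scatter + shape
    if spec.shape_mode == "flip":
        dev2 = -dev
    else:
        dev2 = np.roll(dev, 1)
    return m + spec.elevation_shift + spec.scatter_factor * dev2


def make_profile_change_cohort(
    config: GeneratorConfig,
    change_spec: ChangeSpec,
    noise: bool = True,
    wave_months: tuple[float, float] = (0.0, 19.0),
) -> tuple[LongPanel, pd.DataFrame]:
    """Two-wave scale-level cohort with known per-person change types.

    True wave-1 profiles are multivariate normal with the configured means,
    intercept SDs, and trait correlation.  Wave-2 true profiles apply the
    assigned change transform.  When ``noise`` is on, observed scores add
    independent measurement error per wave with the variance implied by each
    trait's ``target_alpha`` (error SD = intercept_sd * sqrt((1-a)/a)), i.e.
    the trait's retest reliability equals its alpha — the same measurement
    model the no-change null simulation assumes.

    Returns the scale-level panel (self rows only) and a labels table
    (person_id, label) for confusion-matrix tests.
    """
    rng = np.random.default_rng(config.seed)
    traits = config.traits
    k = len(traits)
    means = np.array([t.mean for t in traits])
    sd = np.array([t.intercept_sd for t in traits])
    cov = np.outer(sd, sd) * config.trait_correlation
    alphas = np.array([t.target_alpha for t in traits])
    err_sd = sd * np.sqrt((1.0 - alphas) / alphas) if noise else np.zeros(k)

    labels: list[tuple[str, str]] = []
    rows: list[dict] = []
    pid = 0
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(k))
    for label in CHANGE_LABELS:
        count = change_spec.counts.get(label, 0)
        for _ in range(count):
            pid += 1
            person = f"C{pid:05d}"
            true1 = means + chol @ rng.standard_normal(k)
            true2 = _apply_change(true1, label, change_spec)
            obs1 = true1 + rng.standard_normal(k) * err_sd
            obs2 = true2 + rng.standard_normal(k) * err_sd
            labels.append((person, label))
            for w, (m, obs) in enumerate(
                zip(wave_months, (obs1, obs2)), start=1
            ):
                for j, t in enumerate(traits):
                    rows.append(
                        {
                            "person_id": person,
                            "informant_id": None,
                            "rater_role": "self",
                            "wave": w,
                            "month": m,
                            "variable": t.name,
                            "value": obs[j],
                        }
                    )
    panel = LongPanel(
        pd.DataFrame(rows)[PANEL_COLUMNS],
        item_level=False,
        likert_max=config.likert_max,
    )
    label_df = pd.DataFrame(labels, columns=["person_id", "label"])
    return panel, label_df
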