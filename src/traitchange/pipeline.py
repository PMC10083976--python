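"""End-to-end analysis pipeline.

Stages: obtain panel (read CSV or simulate) -> select one longitudinal
informant per person -> score scales -> growth models per trait and rater ->
rank-order stability -> profile change against a simulated null ->
correlated change.  All outputs are CSV/JSON in the configured directory,
plus a manifest recording seeds, configuration hash, and per-stage counts so
runs are reproducible and exclusions auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from traitchange._version import __version__
from traitchange.core_io import (
    LongPanel,
    ScoringKey,
    read_long_panel,
    read_scoring_key,
    score_scales,
    select_longitudinal_informant,
    write_long_panel,
)
from traitchange.correlated_change import (
    baseline_agreement,
    informant_moderation,
    slope_correlation_matrix,
)
from traitchange.errors import TraitChangeError
from traitchange.growth import (
    compare_linear_quadratic,
    extract_slopes,
    fit_growth,
    test_random_slopes,
)
from traitchange.null_simulation import calibration_from_panel, simulate_null_cutoffs
from traitchange.profile_change import (
    change_summary,
    classify_change,
    compute_profile_distances,
)
from traitchange.rank_order import (
    cross_wave_correlations,
    stability_increase_test,
    temporal_decay_table,
)
from traitchange.synthetic import (
    GeneratorConfig,
    default_bfas_config,
    generate_panel,
    make_scoring_key,
)

logger = logging.getLogger("traitchange.pipeline")

INFORMANT_TYPES = ("family", "friend_roommate")


@dataclass
class PipelineConfig:
    """Configuration for one full analysis run.

    Exactly one of ``input_path`` (long CSV + ``scoring_key_path``) or
    ``generator`` must be provided.  All stochastic stages carry explicit
    seeds: the generator's own seed, ``informant_seed`` for informant
    selection, and ``null_seed`` for the no-change null simulation.
    """

    out_dir: str | Path
    input_path: str | Path | None = None
    scoring_key_path: str | Path | None = None
    generator: GeneratorConfig | None = None
    alpha_threshold: float = 0.01
    informant_seed: int = 11
    null_seed: int = 12
    null_n_sim: int = 50_000
    interval_mass: float = 0.999
    classification_wave_pair: tuple[int, int] | None = None  # default (first,last)
    traits_to_analyze: list[str] | None = None  # default: all scored scales
    min_item_coverage: float = 0.8

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise TraitChangeError(
                "provide exactly one of input_path or generator config"
            )
        if not 0.0 < self.alpha_threshold < 1.0:
            raise TraitChangeError("alpha_threshold must lie in (0, 1)")

    def config_hash(self) -> str:
        payload = {
            "input_path": str(self.input_path),
            "scoring_key_path": str(self.scoring_key_path),
            "generator_seed": None if self.generator is None else self.generator.seed,
            "alpha_threshold": self.alpha_threshold,
            "informant_seed": self.informant_seed,
            "null_seed": self.null_seed,
            "null_n_sim": self.null_n_sim,
            "interval_mass": self.interval_mass,
            "version": __version__,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Paths and in-memory tables produced by one pipeline run."""

    out_dir: Path
    manifest: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _growth_stage(
    scores: LongPanel, traits: list[str], role: str, alpha: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    slope_frames = []
    for trait in traits:
        fit_lin = fit_growth(scores, trait, role, "linear", likelihood="ml")
        fit_quad = fit_growth(scores, trait, role, "quadratic", likelihood="ml")
        lrt_quad = compare_linear_quadratic(fit_lin, fit_quad)
        lrt_rs = test_random_slopes(scores, trait, role)
        lo, hi = fit_lin.slope_ci(0.95)
        slope_p = float(
            fit_lin.fixed_effects.set_index("term").loc["month", "p"]
        )
        rows.append(
            {
                "trait": trait,
                "rater_role": role,
                "slope": fit_lin.slope,
                "ci_low": lo,
                "ci_high": hi,
                "p": slope_p,
                "slope_significant": slope_p < alpha,
                "quad_chi2": lrt_quad.chi2,
                "quad_p": lrt_quad.p,
                "quad_significant": lrt_quad.p < alpha,
                "rs_chi2": lrt_rs.chi2,
                "rs_p": lrt_rs.p,
                "rs_p_mixture": lrt_rs.p_mixture,
                "rs_significant": lrt_rs.p < alpha,
                "n_persons": fit_lin.n_persons,
                "n_obs": fit_lin.n_obs,
                "converged": fit_lin.converged,
            }
        )
        slope_frames.append(extract_slopes(fit_lin))
    return pd.DataFrame(rows), pd.concat(slope_frames, ignore_index=True)


def _rank_order_stage(
    scores: LongPanel, traits: list[str], role: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    test_rows, decay_frames = [], []
    for trait in traits:
        corr = cross_wave_correlations(scores, trait, role)
        decay = temporal_decay_table(corr)
        decay.insert(0, "trait", trait)
        decay.insert(1, "rater_role", role)
        decay["step_ladder"] = decay.attrs.get("step_ladder")
        decay_frames.append(decay)
        try:
            t_ind = stability_increase_test(corr, method="independent")
            t_dep = stability_increase_test(corr, method="dependent")
        except TraitChangeError as exc:
            logger.warning("stability test unavailable for %s/%s: %s", trait, role, exc)
            continue
        test_rows.append(
            {
                "trait": trait,
                "rater_role": role,
                "r_early": t_ind.r_early,
                "n_early": t_ind.n_early,
                "r_late": t_ind.r_late,
                "n_late": t_ind.n_late,
                "z_diff_independent": t_ind.z_diff,
                "p_one_sided_independent": t_ind.p_one_sided,
                "p_two_sided_independent": t_ind.p_two_sided,
                "z_diff_dependent": t_dep.z_diff,
                "p_two_sided_dependent": t_dep.p_two_sided,
            }
        )
    decay_tab = pd.concat(decay_frames, ignore_index=True) if decay_frames else pd.DataFrame()
    return pd.DataFrame(test_rows), decay_tab


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every analysis stage and write the report bundle.

    Raises with the failing stage's name; partial outputs written before the
    failure are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seeds": {
            "generator": None if config.generator is None else config.generator.seed,
            "informant_selection": config.informant_seed,
            "null_simulation": config.null_seed,
        },
        "alpha_threshold": config.alpha_threshold,
        "stages": {},
    }
    tables: dict[str, pd.DataFrame] = {}
    stage = "ingest"
    try:
        if config.generator is not None:
            panel, truth = generate_panel(config.generator)
            key = make_scoring_key(config.generator)
            truth.to_csv(out / "latent_truth.csv", index=False)
            write_long_panel(panel, out / "panel.csv")
        else:
            panel = read_long_panel(config.input_path)
            key = read_scoring_key(config.scoring_key_path)
        manifest["stages"][stage] = {
            "n_rows": len(panel.data),
            "wave_n_self": panel.wave_n("self"),
        }

        stage = "informant_selection"
        selection = select_longitudinal_informant(panel, config.informant_seed)
        panel = selection.panel
        manifest["stages"][stage] = {
            "n_chosen": len(selection.chosen),
            "n_ineligible": len(selection.ineligible),
        }
        # assign informant types for the moderation stage (recorded; when the
        # input carries no informant metadata, types are assigned at random
        # under the informant-selection seed)
        rng = np.random.default_rng(config.informant_seed + 1)
        informant_type = {
            person: INFORMANT_TYPES[int(rng.integers(2))]
            for person in sorted(selection.chosen)
        }

        stage = "scoring"
        scores = score_scales(panel, key, config.min_item_coverage)
        aspects = key.aspects
        domains = key.domains
        all_traits = domains + aspects
        traits = config.traits_to_analyze or all_traits
        analysis_domains = [t for t in traits if t in domains]
        analysis_aspects = [t for t in traits if t in aspects]
        manifest["stages"][stage] = {"n_scale_rows": len(scores.data)}

        roles = sorted(scores.data["rater_role"].unique())
        stage = "growth"
        slope_tables = []
        for role in roles:
            table, slopes = _growth_stage(scores, traits, role, config.alpha_threshold)
            tables[f"growth_{role}"] = table
            table.to_csv(out / f"growth_{role}.csv", index=False)
            slope_tables.append(slopes)
        slope_table = pd.concat(slope_tables, ignore_index=True)
        slope_table.to_csv(out / "person_slopes.csv", index=False)
        manifest["stages"][stage] = {"n_fits": sum(len(tables[f"growth_{r}"]) for r in roles)}

        stage = "rank_order"
        for role in roles:
            tests, decay = _rank_order_stage(scores, traits, role)
            tables[f"stability_{role}"] = tests
            tables[f"decay_{role}"] = decay
            tests.to_csv(out / f"stability_{role}.csv", index=False)
            decay.to_csv(out / f"decay_{role}.csv", index=False)
        manifest["stages"][stage] = {"traits": len(traits)}

        stage = "profile_change"
        summaries = []
        pair = config.classification_wave_pair
        for set_name, set_traits in (
            ("domains5", analysis_domains),
            ("aspects10", analysis_aspects),
        ):
            if len(set_traits) < 2:
                continue
            for role in roles:
                cal = calibration_from_panel(
                    scores, set_traits, item_panel=panel, key=key, rater_role=role
                )
                cutoffs = simulate_null_cutoffs(
                    cal,
                    trait_set=set_name,
                    n_sim=config.null_n_sim,
                    interval_mass=config.interval_mass,
                    seed=config.null_seed,
                )
                cutoffs.to_json(out / f"cutoffs_{set_name}_{role}.json")
                dists = compute_profile_distances(
                    scores,
                    set_traits,
                    rater_role=role,
                    wave_pairs=None if pair is None else [pair],
                    trait_set_name=set_name,
                )
                classified = classify_change(dists, cutoffs)
                classified.to_csv(
                    out / f"profile_distances_{set_name}_{role}.csv", index=False
                )
                summaries.append(change_summary(classified))
        summary = (
            pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
        )
        tables["profile_summary"] = summary
        summary.to_csv(out / "profile_change_summary.csv", index=False)
        manifest["stages"][stage] = {"n_summaries": len(summary)}

        stage = "correlated_change"
        cross = slope_correlation_matrix(slope_table, scope="cross_rater")
        tables["slope_corr_cross"] = cross
        cross.to_csv(out / "slope_corr_cross_rater.csv", index=False)
        for role in roles:
            within = slope_correlation_matrix(
                slope_table, scope="within_rater", rater_role=role
            )
            tables[f"slope_corr_within_{role}"] = within
            within.to_csv(out / f"slope_corr_within_{role}.csv", index=False)
        base = baseline_agreement(scores, traits)
        tables["baseline_agreement"] = base
        base.to_csv(out / "baseline_agreement.csv", index=False)
        if informant_type and "other" in roles:
            moderation = informant_moderation(
                slope_table, informant_type, alpha=config.alpha_threshold
            )
            tables["moderation"] = moderation
            moderation.to_csv(out / "informant_moderation.csv", index=False)
        manifest["stages"][stage] = {"n_cross_traits": len(cross)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        logger.removeHandler(handler)
        handler.close()
        raise TraitChangeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.removeHandler(handler)
    handler.close()
    return ReportBundle(out_dir=out, manifest=manifest, tables=tables)


def default_pipeline_config(out_dir, seed: int = 0, **overrides) -> PipelineConfig:
    """Study-design defaults with the full synthetic generator."""
    gen = default_bfas_config(seed=seed)
    return PipelineConfig(out_dir=out_dir, generator=gen, **overrides)
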