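import numpy as np
import pandas as pd
import pytest

from traitchange.core_io import PANEL_COLUMNS, LongPanel, ScoringKey
from traitchange.synthetic import GeneratorConfig, TraitSpec


def make_scale_panel(values: dict[tuple[str, int], dict[str, float]],
                     wave_months: dict[int, float] | None = None,
                     rater_role: str = "self") -> LongPanel:
    """Build a scale-level panel from {(person, wave): {trait: value}}."""
    if wave_months is None:
        wave_months = {1: 0.0, 2: 6.0, 3: 13.0, 4: 19.0}
    rows = []
    for (person, wave), traits in values.items():
        for trait, value in traits.items():
            rows.append(
                {
                    "person_id": person,
                    "informant_id": None,
                    "rater_role": rater_role,
                    "wave": wave,
                    "month": wave_months[wave],
                    "variable": trait,
                    "value": value,
                }
            )
    return LongPanel(pd.DataFrame(rows)[PANEL_COLUMNS], item_level=False)


def scale_panel_from_array(scores: np.ndarray, months, trait: str = "T",
                           rater_role: str = "self") -> LongPanel:
    """Panel from an (n_persons x n_waves) array, NaN = missing."""
    n, w = scores.shape
    pid = np.repeat([f"P{i}" for i in range(n)], w)
    wave = np.tile(np.arange(1, w + 1), n)
    month = np.tile(np.asarray(months, dtype=float), n)
    df = pd.DataFrame(
        {
            "person_id": pid,
            "informant_id": None,
            "rater_role": rater_role,
            "wave": wave,
            "month": month,
            "variable": trait,
            "value": scores.ravel(),
        }
    ).dropna(subset=["value"])
    return LongPanel(df[PANEL_COLUMNS], item_level=False)


@pytest.fixture
def toy_key() -> ScoringKey:
    """Two aspects of two items each forming one domain; one reversed item."""
    rows = [
        {"item": "a1", "scale": "A1", "domain": "A", "sign": 1},
        {"item": "a2", "scale": "A1", "domain": "A", "sign": -1},
        {"item": "a3", "scale": "A2", "domain": "A", "sign": 1},
        {"item": "a4", "scale": "A2", "domain": "A", "sign": 1},
    ]
    return ScoringKey(pd.DataFrame(rows), require_two_aspects=True)


def single_trait_config(**overrides) -> GeneratorConfig:
    """Fast one-trait generator used by the simulation suites."""
    defaults = dict(
        n_persons=80,
        retention=(1.0, 1.0, 1.0, 1.0),
        likert_discretize=False,
        n_informants=0,
        seed=0,
    )
    trait_kw = {
        k: overrides.pop(k)
        for k in ("fixed_slope", "slope_sd", "residual_sd", "target_alpha",
                  "quad_coef", "intercept_sd", "mean")
        if k in overrides
    }
    defaults.update(overrides)
    trait_kw.setdefault("target_alpha", 1.0)
    trait = TraitSpec(name="T", domain="TD", n_items=2, **trait_kw)
    return GeneratorConfig(traits=[trait], **defaults)


def item_panel(values: np.ndarray, items: list[str], rater_role: str = "self",
               wave: int = 1, month: float = 0.0) -> LongPanel:
    """Item-level single-wave panel from a persons x items matrix."""
    n = values.shape[0]
    rows = []
    for i in range(n):
        for j, item in enumerate(items):
            rows.append(
                {
                    "person_id": f"P{i}",
                    "informant_id": None,
                    "rater_role": rater_role,
                    "wave": wave,
                    "month": month,
                    "variable": item,
                    "value": values[i, j],
                }
            )
    return LongPanel(pd.DataFrame(rows)[PANEL_COLUMNS], item_level=True,
                     likert_bounded=False)
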