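"""CSV readers/writers and packaged study fixtures.

The packaged fixtures transcribe the printed tables of the motivating
study: ingredient chemical composition (table1), experimental-diet and
validation-diet formulations with analyzed chemistry (table2, table3),
per-diet energy-balance means (table4), ingredient-level in vitro / in
vivo energy values with predictions (table5), and the determined vs
calculated / predicted validation comparisons (table6, table7).

Energies are kcal/kg DM throughout; inclusions are % of diet DM.
En-dash/em-dash and thousands-separator cells were normalized when the
tables were transcribed; numeric fixture cells are plain CSV numbers.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

from .types import (
    BalanceObservation,
    DietComponent,
    DietEnergy,
    DietFormulation,
    IngredientComposition,
    IngredientEnergy,
    InVitroRun,
)


class CorruptedFixtureError(RuntimeError):
    """A packaged fixture's checksum does not match the manifest."""


#: sha256 of each packaged fixture file, frozen at transcription time
_MANIFEST = {
    "table1_ingredients.csv": "19a1109037109eb4d8f8e4cdb40fd1962ea8120a8800f8ade9c0a9785635d0a3",
    "table2_diets.csv": "b34dacf061875726442833592d29408e1fd7a3e4e9fa7a0ef8f083337279bb82",
    "table2_analyzed.csv": "efd9ef9800aedc529f85244186fc146c3dc5833f970c4a96b4f6bd101dd8ab89",
    "table3_diets.csv": "75c047487d87c379b70081ce1ddb9a259b3aeac474fca5250c3834ec65aac624",
    "table3_analyzed.csv": "c0e17c670cabcd24107ef79d833c14cbecdc0b08646a09dc9e5202474554f69b",
    "table4_balance.csv": "b939cd953ec26fbb9192d296fd3dba94ccd0be71be89f858140977afe075c1ff",
    "table5_ingredient_energy.csv": "f59f2d6aae87cce54c4e12382cd70de4641cab529d5da4c27fc7c620960f160d",
    "table6_additivity.csv": "d759188c3338638c334f6f6a831b1d561b8fbe803cfa8c1da830240c6bcb0338",
    "table7_prediction.csv": "1fdbd29a1148ae9c2a5c689b79b920e5b2a6c3d284a5c64cdbd8d19db90fac60",
}

_FIXTURE_FILES = {
    "table1": ("table1_ingredients.csv",),
    "table2": ("table2_diets.csv", "table2_analyzed.csv"),
    "table3": ("table3_diets.csv", "table3_analyzed.csv"),
    "table4": ("table4_balance.csv",),
    "table5": ("table5_ingredient_energy.csv",),
    "table6": ("table6_additivity.csv",),
    "table7": ("table7_prediction.csv",),
}

#: ingredient classes of the 20-ingredient panel
INGREDIENT_CLASSES = {
    "corn": "cereal", "wheat": "cereal", "sorghum": "cereal", "barley": "cereal",
    "wheat_flour": "cereal", "brown_rice": "cereal",
    "wheat_middling": "protein", "soybean_meal_1": "protein",
    "soybean_meal_2": "protein", "fermented_soybean_meal": "protein",
    "enzyme_hydrolyzed_soybean_meal": "protein", "extruded_soybean": "protein",
    "soy_protein_concentrate": "protein", "cottonseed_meal": "protein",
    "rapeseed_meal": "protein", "sunflower_meal": "protein", "rice_ddgs": "protein",
    "rice_bran": "bran", "defatted_rice_bran": "bran", "wheat_bran": "bran",
}

#: diet id of the 96.96%-corn diet used as the substitution basal
BASAL_DIET_ID = "1"


def _fixture_bytes(filename: str) -> bytes:
    data = resources.files("feedenergy.data").joinpath(filename).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _MANIFEST[filename]:
        raise CorruptedFixtureError(
            f"{filename}: sha256 {digest} does not match the packaged manifest"
        )
    return data


def _fixture_df(filename: str) -> pd.DataFrame:
    import io as _io

    return pd.read_csv(_io.BytesIO(_fixture_bytes(filename)))


def load_fixture(name: str):
    """Load a packaged table fixture as typed records.

    ``table1`` -> list[IngredientComposition]; ``table2``/``table3`` ->
    list[DietFormulation] (with analyzed GE attached); ``table4`` ->
    list[BalanceObservation] (pseudo-observations: the source prints
    per-diet means, not per-pig records); ``table5``-``table7`` ->
    pandas DataFrames mirroring the printed layouts.
    """
    if name not in _FIXTURE_FILES:
        raise ValueError(
            f"unknown fixture {name!r}; expected one of {sorted(_FIXTURE_FILES)}"
        )
    if name == "table1":
        return dataframe_to_ingredients(_fixture_df("table1_ingredients.csv"))
    if name in ("table2", "table3"):
        comp_file, an_file = _FIXTURE_FILES[name]
        return dataframe_to_formulations(_fixture_df(comp_file), _fixture_df(an_file))
    if name == "table4":
        return dataframe_to_balance(_fixture_df("table4_balance.csv"))
    if name == "table5":
        return _fixture_df("table5_ingredient_energy.csv").set_index("ingredient_id")
    if name == "table6":
        return _fixture_df("table6_additivity.csv")
    # table7: parse censored p-values ("<0.001")
    df = _fixture_df("table7_prediction.csv")
    df["p_censored"] = df["p_value"].astype(str).str.startswith("<")
    df["p_value"] = (
        df["p_value"].astype(str).str.lstrip("<").astype(float)
    )
    return df


# ---------------------------------------------------------------------------
# DataFrame <-> typed record conversion

def dataframe_to_ingredients(df: pd.DataFrame) -> list[IngredientComposition]:
    return [
        IngredientComposition(
            ingredient_id=r.ingredient_id, dm=r.dm, ge=r.ge, cp=r.cp,
            ee=r.ee, ash=r.ash, ndf=r.ndf, adf=r.adf,
        )
        for r in df.itertuples()
    ]


def dataframe_to_formulations(
    comp: pd.DataFrame, analyzed: Optional[pd.DataFrame] = None
) -> list[DietFormulation]:
    ge_by_diet = {}
    if analyzed is not None:
        ge_by_diet = dict(zip(analyzed["diet_id"].astype(str), analyzed["ge"]))
    forms = []
    for diet_id, grp in comp.groupby("diet_id", sort=False):
        comps = tuple(
            DietComponent(
                ingredient_id=r.ingredient_id,
                inclusion=r.inclusion,
                energy_free=bool(r.energy_free),
                is_test=bool(getattr(r, "is_test", 0)),
            )
            for r in grp.itertuples()
        )
        forms.append(
            DietFormulation(
                diet_id=str(diet_id),
                components=comps,
                analyzed_ge=ge_by_diet.get(str(diet_id)),
            )
        )
    return forms


def dataframe_to_balance(df: pd.DataFrame) -> list[BalanceObservation]:
    return [
        BalanceObservation(
            pig_id=str(r.pig_id), batch=int(r.batch), period=int(r.period),
            diet_id=str(r.diet_id), dmi=r.dmi, gei=r.gei, geo=r.geo, geu=r.geu,
            pseudo=bool(getattr(r, "pseudo", 0)),
        )
        for r in df.itertuples()
    ]


def dataframe_to_invitro(df: pd.DataFrame) -> list[InVitroRun]:
    return [
        InVitroRun(
            sample_id=str(r.sample_id), w_t=r.w_t, ge_t=r.ge_t,
            ge_r=r.ge_r, ge_e=r.ge_e, batch=int(getattr(r, "batch", 1)),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# readers for user-supplied CSVs (same schemas as the fixtures)

def read_ingredients(path) -> list[IngredientComposition]:
    return dataframe_to_ingredients(pd.read_csv(path))


def read_formulations(path, analyzed_path=None) -> list[DietFormulation]:
    analyzed = pd.read_csv(analyzed_path) if analyzed_path else None
    return dataframe_to_formulations(pd.read_csv(path), analyzed)


def read_balance(path) -> list[BalanceObservation]:
    return dataframe_to_balance(pd.read_csv(path))


def read_invitro(path) -> list[InVitroRun]:
    return dataframe_to_invitro(pd.read_csv(path))


# ---------------------------------------------------------------------------
# writers

def diet_energies_to_dataframe(energies: Iterable[DietEnergy]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "diet_id": e.diet_id, "ge_d": e.ge_d, "de_d": e.de_d, "me_d": e.me_d,
                "d_coef": e.d_coef, "m_coef": e.m_coef, "n_obs": e.n_obs,
                "cv_de": e.cv_de, "cv_me": e.cv_me,
            }
            for e in energies
        ]
    )


def ingredient_energies_to_dataframe(energies: Iterable[IngredientEnergy]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ingredient_id": e.ingredient_id, "ivde": e.ivde, "de": e.de,
                "me": e.me, "method": e.method, "p_ti": e.p_ti,
                "cv_ivde": e.cv_ivde, "cv_de": e.cv_de, "cv_me": e.cv_me,
            }
            for e in energies
        ]
    )


def balance_to_dataframe(obs: Iterable[BalanceObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pig_id": o.pig_id, "batch": o.batch, "period": o.period,
                "diet_id": o.diet_id, "dmi": o.dmi, "gei": o.gei,
                "geo": o.geo, "geu": o.geu, "pseudo": int(o.pseudo),
            }
            for o in obs
        ]
    )


def invitro_to_dataframe(runs: Iterable[InVitroRun]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id, "w_t": r.w_t, "ge_t": r.ge_t,
                "ge_r": r.ge_r, "ge_e": r.ge_e, "batch": r.batch,
            }
            for r in runs
        ]
    )


def formulations_to_dataframe(forms: Iterable[DietFormulation]) -> pd.DataFrame:
    rows = []
    for f in forms:
        for c in f.components:
            rows.append(
                {
                    "diet_id": f.diet_id, "ingredient_id": c.ingredient_id,
                    "inclusion": c.inclusion, "energy_free": int(c.energy_free),
                    "is_test": int(c.is_test),
                }
            )
    return pd.DataFrame(rows)
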