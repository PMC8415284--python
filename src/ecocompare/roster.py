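"""Species-group roster: identities, taxon classes and lifespans.

The packaged reference roster lists the species groups of a coastal
embayment food web: 23 vertebrate groups, 17 invertebrate groups,
4 primary-producer groups and 5 bacteria/detritus groups.  Vertebrates
and a handful of commercially important invertebrates are age-structured
and carry a lifespan; the remaining groups are biomass pools.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

TAXON_CLASSES = ("vertebrate", "invertebrate", "producer", "bacteria_detritus")

#: The 15 prey categories used when summarising diets.
PREY_CATEGORIES = (
    "Algae", "Bacteria", "Bird", "Cetacea", "Coelenterate", "Crustacean",
    "Detritus", "Echinoderm", "Elasmobranch", "Microzooplankton", "Mollusc",
    "Phytoplankton", "Polychaete", "Teleost", "Tunicate",
)


def _data_path(name: str):
    return importlib.resources.files("ecocompare.data").joinpath(name)


def build_reference_roster() -> pd.DataFrame:
    """Load the packaged reference roster.

    Returns a DataFrame with columns ``group_id``, ``taxon_class``,
    ``is_single_species`` (bool) and ``lifespan`` (years; NaN for
    biomass-pool-only groups).

    Raises
    ------
    FileNotFoundError
        If the packaged fixture is missing or unreadable.
    ValueError
        If the fixture violates the roster invariants.
    """
    path = _data_path("species_groups.csv")
    try:
        with importlib.resources.as_file(path) as p:
            df = pd.read_csv(p)
    except (FileNotFoundError, OSError) as err:
        raise FileNotFoundError(f"roster fixture missing or unreadable: {path}") from err
    df["is_single_species"] = df["is_single_species"].astype(bool)
    validate_roster(df)
    return df


def validate_roster(df: pd.DataFrame) -> None:
    """Check roster invariants; raise ValueError naming the offence."""
    if df["group_id"].duplicated().any():
        dups = df.loc[df["group_id"].duplicated(), "group_id"].tolist()
        raise ValueError(f"duplicate group_ids in roster: {dups}")
    bad_class = set(df["taxon_class"]) - set(TAXON_CLASSES)
    if bad_class:
        raise ValueError(f"unknown taxon classes: {sorted(bad_class)}")
    verts = df[df["taxon_class"] == "vertebrate"]
    if verts["lifespan"].isna().any():
        missing = verts.loc[verts["lifespan"].isna(), "group_id"].tolist()
        raise ValueError(f"vertebrate groups without lifespan: {missing}")


def load_prey_categories() -> pd.DataFrame:
    """Packaged map of every roster group to one of the 15 prey categories."""
    with importlib.resources.as_file(_data_path("prey_categories.csv")) as p:
        df = pd.read_csv(p)
    bad = set(df["category"]) - set(PREY_CATEGORIES)
    if bad:
        raise ValueError(f"unknown prey categories in fixture: {sorted(bad)}")
    return df


def load_skill_table() -> pd.DataFrame:
    """Packaged Pearson skill correlations (survey and CPUE) per group.

    A reference table of correlations between a source-model SSB and
    survey/CPUE index series, used for regression tests of the skill
    statistics.
    """
    with importlib.resources.as_file(_data_path("table6_skill.csv")) as p:
        return pd.read_csv(p)
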