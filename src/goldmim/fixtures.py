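"""Packaged transcriptions of the study's printed tables.

Four small CSV fixtures ship with the package: the species catalogue of
the golden complex (table1), the predator gut-screen percentages (table2),
the defensive traits of the five staged-trial mimics (table3) and the
group-specific primer pairs (table4).  The files are immutable; loading
verifies a SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .predation import GutScreenTable
from .unpalatability import EXTENDED_TRAITS, TraitTable

FIXTURE_FILES = {
    "table1": "table1_catalogue.csv",
    "table2": "table2_gut_screen.csv",
    "table3": "table3_traits.csv",
    "table4": "table4_primers.csv",
}

#: SHA-256 of each packaged fixture (fixtures are immutable)
FIXTURE_SHA256 = {
    "table1": "0bb994a1d725a86996cd68ae76001e34eec98208f33359e081ad2106773eb038",
    "table2": "98c5b8627a23bac37ccf08aae6fbcdf93f2b21940008ffaf6eaf74f423892027",
    "table3": "aea3fde34235898fbead3e16041cfc8fd50dbddb08aaa425f3f55a8c9515f9ed",
    "table4": "63313e6b7e15bdcd824f55d5a57a4d5752732916a952199c4b464a91aaff98c5",
}

VALID_FAMILIES = {"Formicidae", "Mutillidae", "Eurymelidae",
                  "Rhyparochromidae", "Salticidae", "Corinnidae",
                  "Gnaphosidae"}


def _fixture_bytes(name: str) -> bytes:
    try:
        fname = FIXTURE_FILES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; "
                         f"choose from {sorted(FIXTURE_FILES)}") from None
    return resources.files("goldmim.data").joinpath(fname).read_bytes()


def load_fixture(name: str):
    """Load a packaged table by name ('table1' .. 'table4').

    table1 -> species catalogue DataFrame; table2 -> GutScreenTable (the
    printed percentages divided by 100); table3 -> TraitTable with the
    extended trait set; table4 -> primer DataFrame.
    """
    raw = _fixture_bytes(name)
    digest = hashlib.sha256(raw).hexdigest()
    if digest != FIXTURE_SHA256[name]:
        raise RuntimeError(f"fixture {name} checksum mismatch: corrupted install")
    import io
    df = pd.read_csv(io.BytesIO(raw))
    if name == "table1":
        df["form"] = df["form"].fillna("")
        df["subfamily"] = df["subfamily"].fillna("")
        df["subgenus"] = df["subgenus"].fillna("")
        bad = set(df["family"]) - VALID_FAMILIES
        if bad:
            raise ValueError(f"unexpected families in catalogue: {sorted(bad)}")
        key = df[["genus", "species", "form"]].agg(" ".join, axis=1)
        if key.duplicated().any():
            raise ValueError("catalogue rows must be unique by full name + form")
        return df
    if name == "table2":
        return GutScreenTable.from_percent_table(df)
    if name == "table3":
        return TraitTable(df.set_index("species_id"), traits=EXTENDED_TRAITS)
    return df


def load_table2_percent() -> pd.DataFrame:
    """The gut-screen fixture verbatim (percent scale), for inspection."""
    import io
    return pd.read_csv(io.BytesIO(_fixture_bytes("table2")))


def catalogue_counts(cat: pd.DataFrame) -> dict:
    """Species counts per family (forms collapsed) and total entry count.

    Forms of one species (e.g. the colour forms of *Myrmarachne
    erythrocephala*) collapse to a single species for the per-family
    species counts but remain distinct entries in ``total_entries``.
    """
    if len(cat) == 0:
        return {"by_family": {}, "total_entries": 0, "total_species": 0,
                "spider_species": 0}
    species_key = cat[["family", "genus", "species"]].drop_duplicates()
    by_family = species_key.groupby("family").size().to_dict()
    spider_families = {"Salticidae", "Corinnidae", "Gnaphosidae"}
    spiders = int(species_key["family"].isin(spider_families).sum())
    return {
        "by_family": by_family,
        "total_entries": int(len(cat)),
        "total_species": int(len(species_key)),
        "spider_species": spiders,
    }
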