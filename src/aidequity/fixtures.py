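"""Packaged reference tabulations with integrity checks.

Two small plain-text fixtures ship with the package:

``survey_summary.tsv``
    One row per study survey (69 pooled DHS-style surveys, 2003-2012):
    households with complete asset information, under-5 deaths, and
    child-years of exposure (thousands) during the decade preceding each
    survey.

``wealth_description.tsv``
    Sample description by wealth quintile: weighted asset-ownership shares,
    rooms per person, urban residence, and period under-5 mortality rates
    with exposure for 1993-2000 and 2005-2012.

Both are verified against a sha256 + row-count manifest at load time.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

from aidequity.exceptions import FixtureError

_PACKAGE = "aidequity.data"


def _read_verified(name: str) -> bytes:
    root = resources.files(_PACKAGE)
    manifest = json.loads((root / "checksums.json").read_text())
    if name not in manifest:
        raise FixtureError(f"{name} not in fixture manifest")
    data = (root / name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != manifest[name]["sha256"]:
        raise FixtureError(f"{name}: checksum mismatch ({digest})")
    n_rows = data.decode("utf-8").count("\n") - 1
    if n_rows != manifest[name]["n_rows"]:
        raise FixtureError(
            f"{name}: {n_rows} rows, manifest says {manifest[name]['n_rows']}"
        )
    return data


def load_survey_summary() -> pd.DataFrame:
    """The 69-survey summary: households, deaths, child-years per survey."""
    import io

    return pd.read_csv(io.BytesIO(_read_verified("survey_summary.tsv")), sep="\t")


def load_wealth_description() -> pd.DataFrame:
    """Sample description by wealth quintile (variables x quintile columns)."""
    import io

    df = pd.read_csv(
        io.BytesIO(_read_verified("wealth_description.tsv")), sep="\t"
    )
    return df.set_index("variable")


def fixture_totals(summary: pd.DataFrame) -> tuple[float, float, float]:
    """Column sums of the survey summary: (households, deaths, child-years in 1000s).

    An empty table sums to (0, 0, 0).
    """
    if summary.empty:
        return (0.0, 0.0, 0.0)
    return (
        float(summary["households"].sum()),
        float(summary["deaths"].sum()),
        float(summary["child_years_thousands"].sum()),
    )
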