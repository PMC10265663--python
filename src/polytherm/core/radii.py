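"""van der Waals radii lookup.

Ships a Bondi-style table as package data (nm); callers may override
individual entries. Elements missing from the table fall back to the
table's ``default`` entry.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional

import yaml


@lru_cache(maxsize=1)
def _builtin_table() -> dict:
    text = resources.files("polytherm.core").joinpath("data/vdw_radii.yaml").read_text()
    return yaml.safe_load(text)


def load_radii_table(overrides: Optional[Mapping[str, float]] = None) -> dict:
    """Return the vdW radii table (nm), optionally with user overrides applied."""
    table = dict(_builtin_table())
    if overrides:
        table.update({str(k): float(v) for k, v in overrides.items()})
    return table


def vdw_radius(element: str, table: Optional[Mapping[str, float]] = None) -> float:
    """van der Waals radius in nm for an element symbol (case-normalized)."""
    table = table if table is not None else _builtin_table()
    sym = element.strip().capitalize()
    if sym in table:
        return float(table[sym])
    return float(table["default"])
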