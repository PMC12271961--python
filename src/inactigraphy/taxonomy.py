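"""Functional app taxonomy.

Apps are classified into six functional groups:

* ``A`` — network/information (search, browsers, learning, news)
* ``B`` — leisure and entertainment (video, gaming, reading)
* ``C`` — functional utilities (clock, calculator, calendar, email)
* ``D`` — emotional/social (chat, messaging, social media)
* ``E`` — monetary (shopping, banking, trading)
* ``unknown`` — apps with unclear or unspecified primary function

A small default mapping covering well-known apps is bundled; real analyses
should supply their own mapping CSV (columns ``app_id,category``).
Lookup is case-insensitive and total: unmapped ids fall into ``unknown``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

CATEGORIES = ("A", "B", "C", "D", "E", "unknown")


@dataclass(frozen=True)
class CategoryMapping:
    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.entries.values()} - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories in mapping: {sorted(bad)}")
        object.__setattr__(
            self, "entries", {k.strip().lower(): v for k, v in self.entries.items()}
        )

    def lookup(self, app_id: str) -> str:
        return self.entries.get(str(app_id).strip().lower(), "unknown")

    def lookup_series(self, app_ids: pd.Series) -> pd.Series:
        """Vectorized categorization of a column of app ids."""
        out = app_ids.astype(str).str.strip().str.lower().map(self.entries)
        return out.fillna("unknown")

    def apps_in(self, category: str) -> list[str]:
        return sorted(a for a, c in self.entries.items() if c == category)


def load_mapping(path: str | Path) -> CategoryMapping:
    """Load an ``app_id,category`` CSV into a :class:`CategoryMapping`.

    Raises on unknown category tokens and on duplicate app ids (after
    case folding), since a session must receive exactly one category.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("app_id", "category") if c not in df.columns]
    if missing:
        raise ValueError(f"mapping {path} missing required columns: {missing}")
    bad = sorted(set(df["category"]) - set(CATEGORIES))
    if bad:
        raise ValueError(f"unknown category tokens in {path}: {bad}")
    keys = df["app_id"].str.strip().str.lower()
    dup = sorted(set(keys[keys.duplicated()]))
    if dup:
        raise ValueError(f"duplicate app_id in {path}: {dup}")
    return CategoryMapping(dict(zip(keys, df["category"])))


def default_mapping() -> CategoryMapping:
    """The bundled mapping of well-known apps."""
    with resources.as_file(
        resources.files("inactigraphy.data") / "default_app_categories.csv"
    ) as p:
        return load_mapping(p)


def categorize_app(app_id: str, mapping: CategoryMapping | None = None) -> str:
    """Return the functional category of *app_id* (``unknown`` if unmapped)."""
    if mapping is None:
        mapping = default_mapping()
    return mapping.lookup(app_id)
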