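"""Game-type catalog: the fixed list of gambling products a survey asks about.

The default catalog covers the 15 game types of the Icelandic prevalence
surveys (8 terrestrial/offline, 7 online) with one ordinal frequency column
(categories 0 = never ... 5 = daily) and one open-ended usual-spending column
per type. Column names are catalog-driven so any survey export can be bound
without renaming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ConfigError, SchemaError


@dataclass(frozen=True)
class GameType:
    type_id: str
    label: str
    mode: str  # "offline" | "online"
    frequency_column: str = ""
    spending_column: str = ""

    def __post_init__(self):
        if self.mode not in ("offline", "online"):
            raise ConfigError(f"mode must be 'offline' or 'online', got {self.mode!r}")
        if not self.frequency_column:
            object.__setattr__(self, "frequency_column", f"freq_{self.type_id}")
        if not self.spending_column:
            object.__setattr__(self, "spending_column", f"spend_{self.type_id}")


@dataclass
class GameTypeCatalog:
    """Ordered collection of game types with unique ids."""

    entries: list[GameType] = field(default_factory=list)

    def __post_init__(self):
        ids = [e.type_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate type_id in catalog")

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def type_ids(self) -> list[str]:
        return [e.type_id for e in self.entries]

    def get(self, type_id: str) -> GameType:
        for e in self.entries:
            if e.type_id == type_id:
                return e
        raise KeyError(type_id)

    @property
    def frequency_columns(self) -> list[str]:
        return [e.frequency_column for e in self.entries]

    @property
    def spending_columns(self) -> list[str]:
        return [e.spending_column for e in self.entries]

    def by_mode(self, mode: str) -> list[GameType]:
        return [e for e in self.entries if e.mode == mode]

    def validate_columns(self, columns) -> None:
        """Check that every catalog column exists in ``columns``."""
        cols = set(columns)
        for e in self.entries:
            for col in (e.frequency_column, e.spending_column):
                if col not in cols:
                    raise SchemaError(
                        f"survey table is missing column {col!r} required by "
                        f"game type {e.type_id!r}"
                    )

    def subset(self, type_ids) -> "GameTypeCatalog":
        return GameTypeCatalog([self.get(t) for t in type_ids])

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path) -> None:
        data = [
            {
                "type_id": e.type_id,
                "label": e.label,
                "mode": e.mode,
                "frequency_column": e.frequency_column,
                "spending_column": e.spending_column,
            }
            for e in self.entries
        ]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GameTypeCatalog":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls([GameType(**row) for row in data])


#: (type_id, label, mode) for the 15 game types of the Icelandic surveys.
_DEFAULT_TYPES = [
    ("lotto_offline", "Lotto offline", "offline"),
    ("lotto_online_is", "Lotto online on an Icelandic website", "online"),
    ("egm_offline", "Electronic gaming machine offline", "offline"),
    ("scratch_offline", "Scratch cards offline", "offline"),
    ("sportpools_offline", "Betting on sport pools offline", "offline"),
    ("sportpools_online_is", "Betting on sport pools online (Icelandic website)", "online"),
    ("sportbet_offline", "Sport betting offline (fixed odds)", "offline"),
    ("sportbet_online_is", "Sport betting online (Icelandic website)", "online"),
    ("livebet_online", "Live betting online (Icelandic or foreign website)", "online"),
    ("sportbet_online_foreign", "Sport betting online (foreign website)", "online"),
    ("poker_offline", "Poker offline", "offline"),
    ("poker_online_foreign", "Poker online (foreign website)", "online"),
    ("skillbet_offline", "Betting on skill games offline", "offline"),
    ("bingo_offline", "Bingo offline", "offline"),
    ("other_online_foreign", "Other online gambling on foreign websites", "online"),
]


def default_catalog() -> GameTypeCatalog:
    """The 15-type default catalog (8 offline, 7 online)."""
    return GameTypeCatalog([GameType(t, lbl, mode) for t, lbl, mode in _DEFAULT_TYPES])
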