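"""Instrument definition for the RCADS-47 questionnaire.

The Revised Child Anxiety and Depression Scale (RCADS-47) is a 47-item
self-report measure with four ordered response levels
(0 = Never, 1 = Sometimes, 2 = Often, 3 = Always) and six symptom
subscales: major depression (MDD), generalized anxiety (GAD),
obsessive-compulsive (OCD), panic (PD), separation anxiety (SAD) and
social phobia (SP).  The five anxiety subscales together form the
*anxiety* scale; all 47 items form the *internalizing* scale.

The item-to-subscale key ships as an editable YAML resource
(``data/itembank.yaml``); any partition of the 47 items into the six
subscales is accepted, so cohorts scored with a locally adapted key can
reuse the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

N_ITEMS = 47
LEVELS = (0, 1, 2, 3)
SUBSCALES = ("MDD", "GAD", "OCD", "PD", "SAD", "SP")
#: anxiety scale = everything but the depression subscale
ANXIETY_SUBSCALES = ("GAD", "OCD", "PD", "SAD", "SP")

ITEM_COLUMNS = tuple(f"item_{i:02d}" for i in range(1, N_ITEMS + 1))


def item_column(item_id: int) -> str:
    """CSV column name for an item id (1-based)."""
    return f"item_{item_id:02d}"


@dataclass(frozen=True)
class ItemBank:
    """The 47-item instrument: subscale partition plus response levels."""

    subscale_items: dict[str, tuple[int, ...]]
    levels: tuple[int, ...] = LEVELS
    subscale_of: dict[int, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if tuple(sorted(self.levels)) != LEVELS:
            raise ValueError(f"response levels must be {LEVELS}, got {self.levels}")
        if set(self.subscale_items) != set(SUBSCALES):
            raise ValueError(
                f"subscales must be exactly {set(SUBSCALES)}, got {set(self.subscale_items)}"
            )
        seen: dict[int, str] = {}
        for scale, items in self.subscale_items.items():
            for i in items:
                if not (1 <= int(i) <= N_ITEMS):
                    raise ValueError(f"item id {i} outside 1..{N_ITEMS}")
                if i in seen:
                    raise ValueError(f"item {i} assigned to both {seen[i]} and {scale}")
                seen[int(i)] = scale
        if len(seen) != N_ITEMS:
            missing = sorted(set(range(1, N_ITEMS + 1)) - set(seen))
            raise ValueError(f"items not assigned to any subscale: {missing}")
        object.__setattr__(self, "subscale_of", seen)

    @property
    def item_ids(self) -> tuple[int, ...]:
        return tuple(range(1, N_ITEMS + 1))

    def items_of(self, subscale: str) -> tuple[int, ...]:
        return tuple(self.subscale_items[subscale])

    def columns_of(self, subscale: str) -> list[str]:
        return [item_column(i) for i in self.items_of(subscale)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ItemBank":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: dict) -> "ItemBank":
        subscales = {k: tuple(int(i) for i in v) for k, v in raw["subscales"].items()}
        levels = tuple(int(x) for x in raw.get("levels", LEVELS))
        return cls(subscale_items=subscales, levels=levels)


def default_bank() -> ItemBank:
    """Load the packaged standard RCADS-47 scoring key."""
    ref = resources.files("rcads_ml").joinpath("data/itembank.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return ItemBank._from_mapping(raw)
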