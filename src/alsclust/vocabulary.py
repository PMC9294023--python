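"""Column vocabulary and bilateral pairing map for the raw metric tables.

The three raw tables (cortical thickness, volumetry, fractional anisotropy)
carry lateralised columns named ``<base>_lh`` / ``<base>_rh`` plus midline
singletons.  The vocabulary ships as a YAML config so other atlas naming
schemes can be mapped without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

TABLE_NAMES = ("thickness", "volumes", "fa")


@dataclass(frozen=True)
class TableVocabulary:
    """Expected columns of one raw metric table and how they reduce."""

    name: str
    prefix: str
    bilateral: tuple[str, ...]
    midline: tuple[str, ...]

    @property
    def raw_columns(self) -> list[str]:
        cols = []
        for base in self.bilateral:
            cols.extend([f"{base}_lh", f"{base}_rh"])
        cols.extend(self.midline)
        return cols

    @property
    def reduced_columns(self) -> list[str]:
        return [f"{self.prefix}_{base}" for base in (*self.bilateral, *self.midline)]

    def pairing_map(self) -> dict[str, tuple[str, ...]]:
        """Reduced column name -> its 1-2 source columns in the raw table."""
        out: dict[str, tuple[str, ...]] = {}
        for base in self.bilateral:
            out[f"{self.prefix}_{base}"] = (f"{base}_lh", f"{base}_rh")
        for base in self.midline:
            out[f"{self.prefix}_{base}"] = (base,)
        return out


def _default_config_text(filename: str) -> str:
    return resources.files("alsclust.config").joinpath(filename).read_text()


def load_vocabulary(path: str | Path | None = None) -> dict[str, TableVocabulary]:
    """Load the column vocabulary (packaged default unless *path* given)."""
    if path is None:
        raw = yaml.safe_load(_default_config_text("column_vocabulary.yaml"))
    else:
        raw = yaml.safe_load(Path(path).read_text())
    vocab = {}
    for table in TABLE_NAMES:
        if table not in raw:
            raise ValueError(f"vocabulary config missing table {table!r}")
        entry = raw[table]
        vocab[table] = TableVocabulary(
            name=table,
            prefix=entry["prefix"],
            bilateral=tuple(entry["bilateral"]),
            midline=tuple(entry.get("midline") or ()),
        )
    return vocab
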