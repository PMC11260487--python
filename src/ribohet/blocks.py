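"""Block libraries: named residue-range segmentations of a reference model.

A block is a named set of inclusive (chain, start, end) residue ranges with a
category tag. A library is an ordered list of blocks; its order fixes the
column order of every occupancy matrix downstream. The segmentation of the
reference model (e.g. a mature 50S split into ~114 blocks) is user data
supplied in a YAML configuration; this module validates and applies it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .io_formats import AtomicModel

__all__ = [
    "CATEGORIES",
    "BlockSpec",
    "BlockLibrary",
    "load_block_library",
    "save_block_library",
    "extract_block_coords",
    "validate_library",
]

CATEGORIES = ("core", "CP", "PTC", "H68_69", "L1_stalk", "protein", "other")


@dataclass(frozen=True)
class BlockSpec:
    """One named block: inclusive residue ranges plus a category tag."""

    name: str
    selectors: tuple[tuple[str, int, int], ...]  # (chain, first residue, last residue)
    category: str = "other"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("block name must be non-empty")
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"block {self.name!r}: unknown category {self.category!r} "
                f"(expected one of {CATEGORIES})"
            )
        if not self.selectors:
            raise ValidationError(f"block {self.name!r}: at least one selector required")
        for chain, start, end in self.selectors:
            if start > end:
                raise ValidationError(
                    f"block {self.name!r}: inverted range {start}-{end} on chain {chain!r}"
                )

    def contains(self, chain: str, resnum: int) -> bool:
        return any(c == chain and s <= resnum <= e for c, s, e in self.selectors)


@dataclass
class BlockLibrary:
    blocks: list[BlockSpec]
    reference_id: str = ""

    def __post_init__(self) -> None:
        names = [b.name for b in self.blocks]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate block names: {sorted(dupes)}")

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.blocks]

    def __len__(self) -> int:
        return len(self.blocks)

    def __getitem__(self, name: str) -> BlockSpec:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def by_category(self, category: str) -> list[BlockSpec]:
        return [b for b in self.blocks if b.category == category]


def load_block_library(config: str | Path) -> BlockLibrary:
    """Load a block library from a YAML configuration.

    Expected layout::

        reference: 7K00
        blocks:
          - name: H89
            category: PTC
            selectors:
              - {chain: A, start: 2454, end: 2498}

    Order in the file is preserved. Duplicate names, inverted ranges and
    unknown categories raise ValidationError naming the offending block.
    """
    with open(config) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "blocks" not in doc:
        raise ValidationError(f"{config}: configuration must contain a 'blocks' list")
    specs: list[BlockSpec] = []
    for entry in doc["blocks"]:
        try:
            selectors = tuple(
                (str(s["chain"]), int(s["start"]), int(s["end"]))
                for s in entry.get("selectors", [])
            )
            specs.append(
                BlockSpec(
                    name=str(entry["name"]),
                    selectors=selectors,
                    category=str(entry.get("category", "other")),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(
                f"{config}: malformed block entry {entry!r}: {exc}"
            ) from exc
    return BlockLibrary(blocks=specs, reference_id=str(doc.get("reference", "")))


def save_block_library(library: BlockLibrary, path: str | Path) -> None:
    doc = {
        "reference": library.reference_id,
        "blocks": [
            {
                "name": b.name,
                "category": b.category,
                "selectors": [
                    {"chain": c, "start": s, "end": e} for c, s, e in b.selectors
                ],
            }
            for b in library.blocks
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def extract_block_coords(model: AtomicModel, block: BlockSpec) -> np.ndarray:
    """Å coordinates of all and only the atoms in the block's residue ranges.

    Overlapping selectors contribute each atom once (union semantics, applied
    in model atom order). An empty selection returns an empty (0, 3) array;
    callers decide whether that warrants a warning.
    """
    coords = [
        (a.x, a.y, a.z) for a in model.atoms if block.contains(a.chain, a.resnum)
    ]
    return np.array(coords, dtype=float).reshape(-1, 3)


def validate_library(model: AtomicModel, library: BlockLibrary) -> pd.DataFrame:
    """Coverage report: per-block atom counts plus overall assignment fraction.

    Returns a DataFrame with one row per block (columns ``block``,
    ``category``, ``n_atoms``, ``empty``) and attrs ``coverage`` (fraction of
    model atoms assigned to >= 1 block) and ``empty_blocks``.
    """
    rows = []
    assigned = np.zeros(len(model), dtype=bool)
    for block in library.blocks:
        member = np.array(
            [block.contains(a.chain, a.resnum) for a in model.atoms], dtype=bool
        )
        assigned |= member
        rows.append(
            {
                "block": block.name,
                "category": block.category,
                "n_atoms": int(member.sum()),
                "empty": not member.any(),
            }
        )
    report = pd.DataFrame(rows, columns=["block", "category", "n_atoms", "empty"])
    report.attrs["coverage"] = float(assigned.mean()) if len(model) else 0.0
    report.attrs["empty_blocks"] = report.loc[report["empty"], "block"].tolist()
    return report
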