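"""Test assembly and serialization.

Item pairs are laid out into blocks — by default two blocks of 30
items, half real and half pseudo, so chance performance is exactly
50% — and serialized as two JSON documents: a participant-facing
:class:`TestSpec` (surfaces only) and a separate :class:`AnswerKey`
(lexicality labels), kept apart so the file shown to participants
leaks no answers.  A repeat design re-presents each block's items a
second time in a fresh order, which supports item-level response
consistency as a lexicality-free measure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .pairing import ItemPair

__all__ = [
    "LABEL_WORD",
    "LABEL_PSEUDO",
    "TestItem",
    "TestSpec",
    "AnswerKey",
    "assemble_test",
    "write_test",
    "read_test",
]

LABEL_WORD = "word"
LABEL_PSEUDO = "pseudoword"


@dataclass(frozen=True)
class TestItem:
    item_id: str
    surface: str


@dataclass
class TestSpec:
    """Participant-facing test: ordered blocks of surface items."""

    test_id: str
    language: str
    provenance: dict = field(default_factory=dict)
    blocks: list[list[TestItem]] = field(default_factory=list)

    def all_items(self) -> list[TestItem]:
        return [item for block in self.blocks for item in block]

    def item_ids(self) -> set[str]:
        return {item.item_id for block in self.blocks for item in block}

    def block_of(self, item_id: str) -> int:
        for b, block in enumerate(self.blocks):
            if any(item.item_id == item_id for item in block):
                return b
        raise KeyError(item_id)

    def validate(self, allow_repeats: bool = False) -> None:
        """Check id and surface uniqueness.

        In a repeat design every item occurs exactly twice within its
        block (two presentations of one item_id); otherwise ids and
        surfaces are unique test-wide.
        """
        max_occ = 2 if allow_repeats else 1
        seen_elsewhere: set[str] = set()
        for block in self.blocks:
            ids = [item.item_id for item in block]
            if seen_elsewhere & set(ids):
                raise ValueError("item_id shared across blocks")
            surfaces = [item.surface for item in block]
            for values, kind in ((ids, "item_id"), (surfaces, "surface")):
                counts = {v: values.count(v) for v in set(values)}
                bad = {v: c for v, c in counts.items() if c > max_occ}
                if bad:
                    raise ValueError(f"{kind} repeated too often within a block: {bad}")
            seen_elsewhere |= set(ids)
        # surfaces must also be unique across blocks
        per_block_surfaces = [{i.surface for i in b} for b in self.blocks]
        for x in range(len(per_block_surfaces)):
            for y in range(x + 1, len(per_block_surfaces)):
                shared = per_block_surfaces[x] & per_block_surfaces[y]
                if shared:
                    raise ValueError(f"surface appears in multiple blocks: {sorted(shared)}")


@dataclass
class AnswerKey:
    """item_id → lexicality label; must cover the spec exactly."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        for item_id, label in self.labels.items():
            if label not in (LABEL_WORD, LABEL_PSEUDO):
                raise ValueError(f"bad label {label!r} for {item_id}")

    def check_against(self, spec: TestSpec) -> None:
        spec_ids = {i.item_id for i in spec.all_items()}
        if spec_ids != set(self.labels):
            missing = spec_ids - set(self.labels)
            extra = set(self.labels) - spec_ids
            raise ValueError(
                f"answer key does not cover the test "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )


def assemble_test(
    pairs: Sequence[ItemPair],
    n_blocks: int = 2,
    items_per_block: int = 30,
    repeat_items: bool = False,
    seed: int = 0,
    test_id: str = "test",
    language: str = "und",
    provenance: dict | None = None,
) -> tuple[TestSpec, AnswerKey]:
    """Lay out item pairs into balanced blocks.

    Each block holds ``items_per_block`` unique items, half real and
    half pseudo, every one from a distinct pair; with more than one
    block, a pair's real and pseudo member land in different blocks.
    Block order is a seeded shuffle.  With ``repeat_items`` each
    block's items are appended again in a fresh seeded order, doubling
    the block length (the repeat design used with 20-item blocks).
    """
    if items_per_block % 2 != 0:
        raise ValueError("items_per_block must be even for a 50/50 real:pseudo split")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    need = n_blocks * items_per_block // 2
    if len(pairs) < need:
        raise ValueError(f"need {need} pairs for this layout, got {len(pairs)}")
    half = items_per_block // 2

    rng = np.random.default_rng(seed)
    chosen = [pairs[i] for i in rng.permutation(len(pairs))[:need]]

    # Pair group g contributes its real words to block g and its
    # pseudowords to block g+1 (cyclically), so blocks are balanced and
    # no block contains both members of a pair (when n_blocks > 1).
    blocks_items: list[list[tuple[str, str]]] = [[] for _ in range(n_blocks)]
    for g in range(n_blocks):
        group = chosen[g * half : (g + 1) * half]
        for p in group:
            blocks_items[g].append((p.real, LABEL_WORD))
            blocks_items[(g + 1) % n_blocks].append((p.pseudo.surface, LABEL_PSEUDO))

    blocks: list[list[TestItem]] = []
    labels: dict[str, str] = {}
    counter = 0
    for b, entries in enumerate(blocks_items):
        order = rng.permutation(len(entries))
        block = []
        for idx in order:
            surface, label = entries[idx]
            item_id = f"i{counter:04d}"
            counter += 1
            block.append(TestItem(item_id=item_id, surface=surface))
            labels[item_id] = label
        if repeat_items:
            repeat_order = rng.permutation(len(block))
            block = block + [block[i] for i in repeat_order]
        blocks.append(block)

    spec = TestSpec(
        test_id=test_id,
        language=language,
        provenance=dict(provenance or {}),
        blocks=blocks,
    )
    spec.validate(allow_repeats=repeat_items)
    key = AnswerKey(labels=labels)
    key.check_against(spec)
    return spec, key


def write_test(
    spec: TestSpec,
    key: AnswerKey,
    spec_path: str | Path,
    key_path: str | Path,
) -> None:
    """Serialize spec and key as separate JSON documents."""
    key.check_against(spec)
    repeats = any(
        len({i.item_id for i in block}) < len(block) for block in spec.blocks
    )
    spec.validate(allow_repeats=repeats)
    spec_doc = {
        "test_id": spec.test_id,
        "language": spec.language,
        "provenance": spec.provenance,
        "blocks": [
            [{"item_id": i.item_id, "surface": i.surface} for i in block]
            for block in spec.blocks
        ],
    }
    key_doc = {"test_id": spec.test_id, "labels": dict(sorted(key.labels.items()))}
    with open(spec_path, "w", encoding="utf-8") as fh:
        json.dump(spec_doc, fh, ensure_ascii=False, indent=1)
        fh.write("\n")
    with open(key_path, "w", encoding="utf-8") as fh:
        json.dump(key_doc, fh, ensure_ascii=False, indent=1)
        fh.write("\n")


def read_test(spec_path: str | Path, key_path: str | Path) -> tuple[TestSpec, AnswerKey]:
    with open(spec_path, encoding="utf-8") as fh:
        spec_doc = json.load(fh)
    with open(key_path, encoding="utf-8") as fh:
        key_doc = json.load(fh)
    spec = TestSpec(
        test_id=spec_doc["test_id"],
        language=spec_doc["language"],
        provenance=spec_doc.get("provenance", {}),
        blocks=[
            [TestItem(item_id=i["item_id"], surface=i["surface"]) for i in block]
            for block in spec_doc["blocks"]
        ],
    )
    key = AnswerKey(labels=dict(key_doc["labels"]))
    key.check_against(spec)
    return spec, key
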