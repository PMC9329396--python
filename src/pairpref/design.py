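"""Randomized individual paired-comparison plans.

Each subject receives their own randomized list of ordered pairs, subject to
the study's two constraints: at most ``max_per_subject`` judgments per
subject, and no unordered pair repeated within one subject's plan (a swapped
repeat would still be a re-judgment of the same combination).  Presentation
order within a selected pair is a fair coin flip.  A design is a pure
function of (items, n_subjects, max_per_subject, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from .data_model import DataError, ItemSet

__all__ = ["StudyDesign", "ordered_pairs", "make_design"]


@dataclass(frozen=True)
class StudyDesign:
    """Per-subject randomized lists of ordered (first, second) pairs."""

    plans: dict[str, list[tuple[str, str]]]
    seed: int

    @property
    def n_judgments(self) -> int:
        return sum(len(p) for p in self.plans.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (subject, pos + 1, first, second)
            for subject, plan in self.plans.items()
            for pos, (first, second) in enumerate(plan)
        ]
        return pd.DataFrame(
            rows, columns=["subject", "position_in_session", "first", "second"]
        )

    def write_csv(self, dest: str | Path | IO[str]) -> None:
        self.to_frame().to_csv(dest, index=False)


def ordered_pairs(items: ItemSet) -> list[tuple[str, str]]:
    """All m·(m−1) ordered pairs in deterministic lexicographic order.

    Eight items yield the study's 56 distinct pairings.
    """
    return list(itertools.permutations(items, 2))


def unordered_pairs(items: ItemSet) -> list[tuple[str, str]]:
    """All m·(m−1)/2 unordered combinations, lexicographic."""
    return list(itertools.combinations(items, 2))


def make_design(
    items: ItemSet,
    n_subjects: int,
    max_per_subject: int,
    seed: int,
    balance: bool = False,
) -> StudyDesign:
    """Draw a randomized study design.

    For each subject, ``max_per_subject`` unordered combinations are sampled
    without replacement, then the presentation order of every selected pair
    is randomized by a fair coin flip.  One seeded stream drives the whole
    design; subjects are drawn sequentially, so the design is reproducible
    from the single integer *seed*.

    With ``balance=True``, combinations already used by earlier subjects are
    down-weighted (weight 1/(1+uses)) to even out per-pair totals; the
    default leaves selection uniform, which matches the near- but not
    exactly balanced totals such studies exhibit.
    """
    combos = unordered_pairs(items)
    if max_per_subject > len(combos):
        raise DataError(
            f"max_per_subject={max_per_subject} exceeds the "
            f"{len(combos)} distinct unordered pairs"
        )
    if n_subjects < 0 or max_per_subject < 0:
        raise DataError("n_subjects and max_per_subject must be nonnegative")

    rng = np.random.default_rng(seed)
    usage = np.zeros(len(combos), dtype=np.int64)
    plans: dict[str, list[tuple[str, str]]] = {}
    width = max(2, len(str(max(n_subjects, 1))))
    for s in range(n_subjects):
        if balance:
            w = 1.0 / (1.0 + usage)
            prob = w / w.sum()
        else:
            prob = None
        chosen = rng.choice(len(combos), size=max_per_subject, replace=False, p=prob)
        usage[chosen] += 1
        plan = []
        for k in chosen:
            a, b = combos[k]
            if rng.random() < 0.5:
                a, b = b, a
            plan.append((a, b))
        plans[f"s{s + 1:0{width}d}"] = plan
    return StudyDesign(plans=plans, seed=seed)
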