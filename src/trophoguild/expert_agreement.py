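"""Agreement between independent trophic classification schemes.

Schemes from different sources are standardized to five broad guilds
(herbivores and detritivores, invertivores, omnivores, planktivores,
piscivores); every pair of schemes sharing enough species is compared
through a confusion matrix, with agreement measured as the proportion
of shared species given the same guild. Schemes lacking a category are
compared only over the guilds both schemes define.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BROAD_GUILDS",
    "ClassificationScheme",
    "ConfusionMatrix",
    "standardize_scheme",
    "pairwise_agreement",
    "agreement_summary",
]

BROAD_GUILDS: tuple[str, ...] = (
    "herbivores and detritivores",
    "invertivores",
    "omnivores",
    "planktivores",
    "piscivores",
)


@dataclass
class ClassificationScheme:
    """One source's species -> guild assignment over a declared vocabulary."""

    scheme_id: str
    labels: dict[str, str]
    vocabulary: tuple[str, ...] = BROAD_GUILDS

    def __post_init__(self) -> None:
        vocab = set(self.vocabulary)
        bad = {v for v in self.labels.values() if v not in vocab}
        if bad:
            raise ValueError(
                f"scheme {self.scheme_id}: labels outside vocabulary: {sorted(bad)}"
            )

    @property
    def species(self) -> set[str]:
        return set(self.labels)


@dataclass
class ConfusionMatrix:
    """Cross-tabulation of two schemes' labels over their shared species."""

    table: pd.DataFrame  # rows: scheme 1 labels, cols: scheme 2 labels
    scheme_ids: tuple[str, str]
    n_shared: int = field(init=False)
    agreement: float = field(init=False)

    def __post_init__(self) -> None:
        self.n_shared = int(self.table.values.sum())
        diag = sum(
            self.table.at[g, g]
            for g in self.table.index
            if g in self.table.columns
        )
        self.agreement = float(diag / self.n_shared) if self.n_shared else float("nan")


def standardize_scheme(scheme_id: str, raw: dict[str, str],
                       crosswalk: dict[str, str]) -> ClassificationScheme:
    """Convert a raw scheme's labels to the five broad guilds.

    ``crosswalk`` maps each original category to a broad guild. The
    scheme's vocabulary is the set of broad guilds its original
    categories can express (the crosswalk's targets); a scheme whose
    category list cannot express, say, piscivores is marked as lacking
    that guild, and downstream comparisons are restricted to guilds
    shared by both schemes of a pair.
    """
    if not raw:
        raise ValueError(f"scheme {scheme_id}: no species")
    unmapped = sorted({lab for lab in raw.values() if lab not in crosswalk})
    if unmapped:
        raise ValueError(f"scheme {scheme_id}: unmapped label(s): {unmapped}")
    labels: dict[str, str] = {}
    for sp, lab in raw.items():
        if sp in labels:
            logger.warning("scheme %s: duplicated species %s, last entry wins",
                           scheme_id, sp)
        labels[sp] = crosswalk[lab]
    vocab = tuple(g for g in BROAD_GUILDS if g in set(crosswalk.values()))
    return ClassificationScheme(scheme_id=scheme_id, labels=labels, vocabulary=vocab)


def pairwise_agreement(s1: ClassificationScheme, s2: ClassificationScheme,
                       min_shared: int = 50) -> ConfusionMatrix | None:
    """Confusion matrix between two schemes over their shared species.

    Comparison is restricted to the guilds both schemes define; pairs
    sharing fewer than ``min_shared`` species are skipped (None).
    """
    vocab = [g for g in s1.vocabulary if g in s2.vocabulary]
    shared = [sp for sp in s1.labels
              if sp in s2.labels
              and s1.labels[sp] in vocab and s2.labels[sp] in vocab]
    if len(shared) < min_shared:
        logger.info("pair (%s, %s): %d shared species < %d, skipped",
                    s1.scheme_id, s2.scheme_id, len(shared), min_shared)
        return None
    table = pd.DataFrame(0, index=vocab, columns=vocab, dtype=int)
    for sp in shared:
        table.at[s1.labels[sp], s2.labels[sp]] += 1
    return ConfusionMatrix(table=table, scheme_ids=(s1.scheme_id, s2.scheme_id))


def agreement_summary(schemes: list[ClassificationScheme],
                      min_shared: int = 50) -> dict:
    """Per-pair agreements, their median, and per-guild agreement.

    Per-guild agreement for guild ``g`` in a pair is the fraction of
    one scheme's ``g``-species that the other scheme also labels ``g``,
    pooled over both orderings and averaged (unweighted) over pairs.
    """
    if len(schemes) < 2:
        raise ValueError("need at least 2 schemes")
    pair_rows = []
    per_guild: dict[str, list[float]] = {}
    matrices = []
    for s1, s2 in itertools.combinations(schemes, 2):
        cm = pairwise_agreement(s1, s2, min_shared=min_shared)
        if cm is None:
            continue
        matrices.append(cm)
        pair_rows.append({
            "scheme_1": s1.scheme_id, "scheme_2": s2.scheme_id,
            "n_shared": cm.n_shared, "agreement": cm.agreement,
        })
        t = cm.table
        for g in t.index:
            row_n = t.loc[g].sum()
            col_n = t[g].sum()
            vals = per_guild.setdefault(g, [])
            if row_n:
                vals.append(float(t.at[g, g] / row_n))
            if col_n:
                vals.append(float(t.at[g, g] / col_n))
    if not pair_rows:
        raise ValueError("no scheme pair meets the min_shared threshold")
    pairs = pd.DataFrame(pair_rows)
    guild_mean = pd.Series(
        {g: (float(np.mean(v)) if v else float("nan"))
         for g, v in per_guild.items()},
        name="agreement",
    )
    return {
        "pairs": pairs,
        "median_agreement": float(pairs["agreement"].median()),
        "per_guild": guild_mean,
        "matrices": matrices,
    }
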