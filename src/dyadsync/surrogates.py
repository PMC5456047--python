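"""Virtual-pair surrogate baselines.

Task-level baseline coordination is estimated by re-pairing each
devil's advocate with a naive participant from a DIFFERENT dyad in the
same condition cell (same veracity and conflict labels) and recomputing
every coordination metric on these pseudo-dyads.  Re-pairing breaks the
real-time perceptual coupling between partners while preserving each
participant's own behavioral statistics, so any apparent coordination
left in virtual pairs reflects the task, not the interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import InfeasiblePairingError
from .crqa import EmbeddingParams
from .records import (ConversationRecord, DyadRecord, analyze_pair,
                      flatten_conversations, metrics_row)
from .wlcc import WlccParams

__all__ = ["PairingPlan", "make_virtual_pairs", "surrogate_metrics"]


@dataclass(frozen=True)
class PairingPlan:
    """Seeded derangement of conversations within condition cells.

    Each entry pairs the DA of one conversation with the naive
    participant of another; no entry joins members of the same original
    dyad, and every conversation appears exactly once on each side.
    """

    pairs: tuple[tuple[str, str], ...]
    seed: int

    def __len__(self) -> int:
        return len(self.pairs)


def _derange(ids: list[str], dyads: list[str],
             rng: np.random.Generator, max_tries: int = 10_000) -> list[int]:
    """Random permutation with no index mapped to its own dyad."""
    n = len(ids)
    idx = np.arange(n)
    for _ in range(max_tries):
        perm = rng.permutation(n)
        if all(dyads[i] != dyads[perm[i]] for i in range(n)):
            return perm.tolist()
    raise InfeasiblePairingError(
        "could not find a valid derangement (too few distinct dyads?)")


def make_virtual_pairs(dataset: list[DyadRecord], seed: int) -> PairingPlan:
    """Build a seeded virtual-pair plan over all condition cells.

    Within every (veracity, conflict) cell the conversations are
    re-paired by a random derangement with respect to dyad membership.
    A cell containing conversations from fewer than two distinct dyads
    is infeasible.
    """
    rng = np.random.default_rng(seed)
    convs = flatten_conversations(dataset)
    cells: dict[tuple[str, str], list[ConversationRecord]] = {}
    for c in convs:
        cells.setdefault(c.condition, []).append(c)

    pairs: list[tuple[str, str]] = []
    for cond in sorted(cells):
        group = sorted(cells[cond], key=lambda c: c.conversation_id)
        dyads = [c.dyad_id for c in group]
        if len(set(dyads)) < 2:
            raise InfeasiblePairingError(
                f"condition cell {cond} has conversations from "
                f"{len(set(dyads))} dyad(s); need >= 2")
        perm = _derange([c.conversation_id for c in group], dyads, rng)
        pairs.extend((group[i].conversation_id, group[perm[i]].conversation_id)
                     for i in range(len(group)))
    return PairingPlan(pairs=tuple(pairs), seed=seed)


def surrogate_metrics(
    dataset: list[DyadRecord],
    plan: PairingPlan,
    wlcc_params: WlccParams = WlccParams(),
    emb_params: EmbeddingParams = EmbeddingParams(),
) -> pd.DataFrame:
    """Recompute all coordination metrics on the virtual pairs of ``plan``.

    The DA channels come from the first conversation of each pair and
    the naive channels from the second; unequal series are right-
    truncated to the common length inside :func:`analyze_pair`.  The
    output schema matches the real-pair metrics table, with
    ``pairing_type='virtual'`` and ``virtual_naive_conversation_id``
    recording the provenance of the naive member.
    """
    by_id = {c.conversation_id: c for c in flatten_conversations(dataset)}
    rows = []
    for da_id, naive_id in plan.pairs:
        cda, cna = by_id[da_id], by_id[naive_id]
        metrics = analyze_pair(
            cda.head_da, cna.head_naive,
            cda.lower_da, cna.lower_naive,
            cda.rate_da, cna.rate_naive,
            wlcc_params, emb_params)
        row = metrics_row(cda, "virtual", metrics)
        row["virtual_naive_conversation_id"] = naive_id
        rows.append(row)
    return pd.DataFrame(rows)


def plan_to_frame(plan: PairingPlan) -> pd.DataFrame:
    """Pairing plan as an auditable table."""
    return pd.DataFrame(plan.pairs,
                        columns=["da_conversation_id", "naive_conversation_id"])
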