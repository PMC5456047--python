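"""Dataset containers and the shared per-pair metric computation.

A dyad contributes two conversations (one deceptive, one truthful, in
counterbalanced order); conflict (agree/disagree) is constant within a
dyad, as are the participants' roles (devil's advocate vs naive).  Each
conversation carries per-participant channels: head and lower-body
movement-displacement series at 6 Hz and a 3 Hz estimated-syllable-rate
series, plus the raw utterance tiers and onset events when present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .core import InputError, UniformSeries
from .crqa import EmbeddingParams, crqa_metrics
from .wlcc import WlccParams, lag_bin_features, lag_profile, summarize

__all__ = ["ConversationRecord", "DyadRecord", "flatten_conversations",
           "analyze_pair", "METRIC_COLUMNS"]


@dataclass
class ConversationRecord:
    """One conversation of one dyad, with all channel series."""

    dyad_id: str
    conversation_id: str
    veracity: str            # deception | truth
    conflict: str            # disagree | agree
    order: int               # 1 | 2
    sex_composition: str = "unknown"
    head_da: UniformSeries | None = None
    head_naive: UniformSeries | None = None
    lower_da: UniformSeries | None = None
    lower_naive: UniformSeries | None = None
    rate_da: UniformSeries | None = None
    rate_naive: UniformSeries | None = None
    raw: dict[str, Any] = field(default_factory=dict)

    @property
    def condition(self) -> tuple[str, str]:
        return (self.veracity, self.conflict)


@dataclass
class DyadRecord:
    """One dyad: two conversations with fixed roles and conflict."""

    dyad_id: str
    conflict: str
    sex_composition: str = "unknown"
    conversations: list[ConversationRecord] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.conversations) != 2:
            raise InputError(f"dyad {self.dyad_id} must have 2 conversations")
        veracities = sorted(c.veracity for c in self.conversations)
        if veracities != ["deception", "truth"]:
            raise InputError(
                f"dyad {self.dyad_id} needs one deceptive and one truthful "
                f"conversation, got {veracities}")
        if any(c.conflict != self.conflict for c in self.conversations):
            raise InputError(f"conflict varies within dyad {self.dyad_id}")


def flatten_conversations(dataset: list[DyadRecord]) -> list[ConversationRecord]:
    return [c for d in dataset for c in d.conversations]


METRIC_COLUMNS = (
    ["dyad_id", "conversation_id", "veracity", "conflict", "order",
     "pairing_type"]
    + ["head_lag0", "head_da_follows_1000", "head_naive_follows_1000"]
    + [f"head_bin_{b:+d}" for b in range(-3, 4)]
    + ["lower_lag0", "lower_da_follows_1000", "lower_naive_follows_1000"]
    + [f"lower_bin_{b:+d}" for b in range(-3, 4)]
    + ["RR", "DET", "L", "LMAX", "T2", "ENTR"]
)


def _truncate_pair(a: UniformSeries, b: UniformSeries
                   ) -> tuple[UniformSeries, UniformSeries]:
    n = min(len(a), len(b))
    return a.truncated(n), b.truncated(n)


def analyze_pair(
    head_da: UniformSeries, head_naive: UniformSeries,
    lower_da: UniformSeries, lower_naive: UniformSeries,
    rate_da: UniformSeries, rate_naive: UniformSeries,
    wlcc_params: WlccParams = WlccParams(),
    emb_params: EmbeddingParams = EmbeddingParams(),
) -> dict[str, float]:
    """Compute all coordination metrics for one (possibly virtual) pair.

    Unequal-length channels are right-truncated to the common length.
    Returns a flat dict: WLCC summaries and 1000-ms lag-bin means for
    head and lower body, plus the six CRQA indices of the speech-rate
    pair.  CRQA failures on degenerate series (zero variance) surface
    as NaN metrics rather than aborting the batch.
    """
    out: dict[str, float] = {}
    for region, da_s, na_s in (("head", head_da, head_naive),
                               ("lower", lower_da, lower_naive)):
        da_t, na_t = _truncate_pair(da_s, na_s)
        prof = lag_profile(da_t, na_t, wlcc_params)
        summ = summarize(prof)
        out[f"{region}_lag0"] = summ.lag0
        out[f"{region}_da_follows_1000"] = summ.da_follows_1000
        out[f"{region}_naive_follows_1000"] = summ.naive_follows_1000
        for b, v in lag_bin_features(prof).items():
            out[f"{region}_bin_{b:+d}"] = v

    ra, rb = _truncate_pair(rate_da, rate_naive)
    try:
        metrics = crqa_metrics(ra, rb, emb_params)
        out.update(metrics.as_dict())
    except Exception:  # zero-variance rate series in a degenerate pair
        out.update({k: np.nan for k in ("RR", "DET", "L", "LMAX", "T2", "ENTR")})
    return out


def metrics_row(conv: ConversationRecord, pairing_type: str,
                metrics: dict[str, float]) -> dict[str, Any]:
    row: dict[str, Any] = {
        "dyad_id": conv.dyad_id,
        "conversation_id": conv.conversation_id,
        "veracity": conv.veracity,
        "conflict": conv.conflict,
        "order": conv.order,
        "pairing_type": pairing_type,
    }
    row.update(metrics)
    return row
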