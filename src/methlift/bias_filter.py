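"""Empirical platform-bias filtering from paired same-sample experiments.

Some probe designs read systematically differently on two platforms even for
identical DNA.  When the same cell line has been profiled on both platforms,
those biases are observable directly: a mapping pair is *high confidence*
when the absolute beta difference between its two probes stays within a
threshold (default 0.05) in enough paired experiments (default 4).  Filtering
a mapping down to its high-confidence pairs improves conversion fidelity at
the cost of dropping probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .probe_identity import MappingPair, MappingTable

logger = logging.getLogger(__name__)

__all__ = [
    "PairedExperiment",
    "build_high_confidence_mapping",
    "apply_bias_filter",
    "DEFAULT_DELTA",
    "DEFAULT_MIN_PAIRS",
]

#: Shipped defaults: beta-difference tolerance and the number of concordant
#: paired experiments a mapping pair must reach to count as high confidence.
DEFAULT_DELTA = 0.05
DEFAULT_MIN_PAIRS = 4


@dataclass
class PairedExperiment:
    """One sample profiled on both platforms (e.g. one cell line).

    ``source_betas`` / ``target_betas`` map probe full-IDs to beta values on
    platforms A and B respectively.
    """

    label: str
    source_betas: Mapping[str, float] = field(default_factory=dict)
    target_betas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for side in (self.source_betas, self.target_betas):
            for fid, v in side.items():
                if not np.isnan(v) and not 0.0 <= v <= 1.0:
                    raise ValueError(f"{self.label}: beta for {fid} out of [0,1]: {v}")


def build_high_confidence_mapping(
    mapping: MappingTable,
    experiments: Sequence[PairedExperiment],
    delta: float = DEFAULT_DELTA,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> MappingTable:
    """Set each pair's high-confidence flag from paired-experiment agreement.

    A pair (s, t) is high confidence iff |beta_A(s) - beta_B(t)| <= delta
    (inclusive) in at least ``min_pairs`` experiments where both readings are
    present.  Experiments missing either reading do not count toward
    ``min_pairs``, so a pair observed in fewer than ``min_pairs`` experiments
    is flagged false; the number of such under-observed pairs is logged.
    The pair set itself is unchanged — only the flags are rewritten.
    """
    if not experiments:
        raise ValueError("at least one paired experiment is required")
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    if not 1 <= min_pairs <= len(experiments):
        raise ValueError(
            f"min_pairs must lie in [1, {len(experiments)}], got {min_pairs}"
        )

    src_ids = [p.source_id for p in mapping.pairs]
    tgt_ids = [p.target_id for p in mapping.pairs]
    concordant = np.zeros(len(mapping.pairs), dtype=int)
    evaluable = np.zeros(len(mapping.pairs), dtype=int)
    for exp in experiments:
        s = pd.Series(exp.source_betas, dtype=float).reindex(src_ids).to_numpy()
        t = pd.Series(exp.target_betas, dtype=float).reindex(tgt_ids).to_numpy()
        both = ~(np.isnan(s) | np.isnan(t))
        evaluable += both
        concordant += both & (np.abs(s - t) <= delta)

    under_observed = int((evaluable < min_pairs).sum())
    if under_observed:
        logger.info(
            "build_high_confidence_mapping: %d pairs evaluable in fewer than "
            "%d experiments; flagged low confidence",
            under_observed,
            min_pairs,
        )
    flags = concordant >= min_pairs
    pairs = [
        MappingPair(s, t, bool(f)) for s, t, f in zip(src_ids, tgt_ids, flags)
    ]
    return MappingTable(mapping.source_platform, mapping.target_platform, pairs)


def apply_bias_filter(mapping: MappingTable) -> MappingTable:
    """Keep only the high-confidence pairs of a flagged mapping."""
    kept = [p for p in mapping.pairs if p.high_confidence]
    if not kept:
        logger.warning("apply_bias_filter: no high-confidence pairs remain")
    return MappingTable(mapping.source_platform, mapping.target_platform, kept)
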