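"""Beta-value matrix conversion between platforms.

A beta value is the per-probe methylation level M/(M+U+offset), bounded in
[0,1].  Converting a matrix to another platform walks the prefix-matched
probe mapping: when several source replicates feed one target probe their
readings are aggregated (arithmetic mean, or the replicate with the most
significant detection p-value); when one source probe fans out to several
target replicates its reading is broadcast to each of them.  Aggregation is
per sample, never pooled across samples, and missing values stay missing —
they are skipped, never treated as zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .probe_identity import MappingTable

logger = logging.getLogger(__name__)

__all__ = [
    "BetaMatrix",
    "aggregate_replicates",
    "convert_beta",
    "read_beta_tsv",
    "write_beta_tsv",
]

STRATEGIES = ("mean", "best_detection")


@dataclass
class BetaMatrix:
    """Probes x samples methylation-level matrix.

    ``values`` is a float DataFrame indexed by probe full-IDs with one column
    per sample; missing readings are NaN and every non-missing entry lies in
    [0, 1].
    """

    platform: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()][:5]
            raise ValueError(f"duplicate probe IDs in beta matrix: {list(dups)}")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def aggregate_replicates(
    values: Sequence[float],
    strategy: str = "mean",
    detection_p: Sequence[float] | None = None,
    masked: Sequence[bool] | None = None,
) -> float:
    """Collapse replicate readings of one CpG for one sample to one beta.

    ``mean`` averages the non-missing values (NaN if all are missing).
    ``best_detection`` returns the value whose detection p-value is smallest
    among unmasked candidates with a non-missing value; ties break to the
    candidate earliest in the (caller-ordered) sequence, which convert_beta
    arranges to be the lexicographically lowest probe ID.  When no candidate
    is eligible (all masked, or all p-values missing) the strategy falls back
    to the mean of non-missing values.
    """
    if len(values) == 0:
        raise ValueError("aggregate_replicates requires at least one value")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    arr = np.asarray(values, dtype=float)

    if strategy == "mean":
        finite = arr[~np.isnan(arr)]
        return float(finite.mean()) if finite.size else math.nan

    if detection_p is None:
        raise ValueError("strategy 'best_detection' requires detection_p")
    p = np.asarray(detection_p, dtype=float)
    if p.shape != arr.shape:
        raise ValueError("detection_p must align with values")
    if np.any((~np.isnan(p)) & ((p < 0) | (p > 1))):
        raise ValueError("detection p-values must lie in [0, 1]")
    msk = np.zeros(arr.shape, dtype=bool) if masked is None else np.asarray(masked, dtype=bool)

    eligible = (~np.isnan(arr)) & (~np.isnan(p)) & (~msk)
    if not eligible.any():
        finite = arr[~np.isnan(arr)]
        return float(finite.mean()) if finite.size else math.nan
    # np.argmin on a masked copy: first occurrence wins ties.
    p_masked = np.where(eligible, p, np.inf)
    return float(arr[int(np.argmin(p_masked))])


def _detection_frame(
    signal: object,
    sample_ids: Sequence[str],
) -> tuple[pd.DataFrame | None, pd.DataFrame | None]:
    """Normalize the optional per-sample signal input to (p, mask) frames.

    Accepts a single SignalFrame (applied to every sample) or a mapping
    sample_id -> SignalFrame.  Returns probe x sample DataFrames of detection
    p-values and mask flags, or (None, None) when no signal is given.
    """
    from .signal_liftover import SignalFrame  # local import to avoid a cycle

    if signal is None:
        return None, None
    if isinstance(signal, SignalFrame):
        p = pd.DataFrame({s: signal.data["detection_p"] for s in sample_ids})
        m = pd.DataFrame({s: signal.data["masked"] for s in sample_ids})
        return p, m
    if isinstance(signal, Mapping):
        missing = [s for s in sample_ids if s not in signal]
        if missing:
            raise ValueError(f"no signal frame supplied for samples {missing[:5]}")
        p = pd.DataFrame({s: signal[s].data["detection_p"] for s in sample_ids})
        m = pd.DataFrame({s: signal[s].data["masked"] for s in sample_ids})
        return p, m.fillna(False).astype(bool)
    raise TypeError("signal must be a SignalFrame or a mapping sample_id -> SignalFrame")


def convert_beta(
    b: BetaMatrix,
    mapping: MappingTable,
    strategy: str = "mean",
    signal: object = None,
    respect_mask: bool = False,
) -> BetaMatrix:
    """Convert a beta matrix onto the mapping's target platform.

    Output rows are the distinct target IDs of the mapping in lexicographic
    order; each cell aggregates the readings of the source probes feeding that
    target (see :func:`aggregate_replicates`).  Sample columns are preserved.
    Target probes with no source feed are absent — the imputation module fills
    them.  Mapping pairs whose source probe is missing from ``b`` are skipped
    with a logged count.

    ``respect_mask`` excludes masked source probes under the ``mean`` strategy
    too (they are always excluded from best_detection candidacy).
    """
    if b.platform != mapping.source_platform:
        raise ValueError(
            f"matrix platform {b.platform!r} != mapping source {mapping.source_platform!r}"
        )
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    p_frame, mask_frame = _detection_frame(signal, b.sample_ids)
    if strategy == "best_detection" and p_frame is None:
        raise ValueError("strategy 'best_detection' requires a signal frame with detection p-values")

    present = set(b.values.index)
    pairs = [(p.source_id, p.target_id) for p in mapping.pairs]
    skipped = sum(1 for s, _ in pairs if s not in present)
    if skipped:
        logger.info("convert_beta: skipped %d mapping pairs with no source reading", skipped)
    pairs = [(s, t) for s, t in pairs if s in present]

    by_target: dict[str, list[str]] = {}
    for s, t in pairs:
        by_target.setdefault(t, []).append(s)

    target_ids = sorted(by_target)
    samples = b.sample_ids
    out = np.full((len(target_ids), len(samples)), np.nan)

    for i, tgt in enumerate(target_ids):
        sources = sorted(by_target[tgt])  # lexicographic tie-break order
        vals = b.values.loc[sources].to_numpy(dtype=float)  # sources x samples
        if p_frame is not None:
            p = p_frame.reindex(index=sources, columns=samples).to_numpy(dtype=float)
            msk = (
                mask_frame.reindex(index=sources, columns=samples)
                .fillna(False)
                .to_numpy(dtype=bool)
            )
        else:
            p = None
            msk = np.zeros(vals.shape, dtype=bool)
        for j in range(len(samples)):
            col = vals[:, j]
            if strategy == "mean":
                use = col if not respect_mask else np.where(msk[:, j], np.nan, col)
                finite = use[~np.isnan(use)]
                out[i, j] = finite.mean() if finite.size else np.nan
            else:
                out[i, j] = aggregate_replicates(
                    col, "best_detection", detection_p=p[:, j], masked=msk[:, j]
                )

    frame = pd.DataFrame(out, index=pd.Index(target_ids, name="Probe_ID"), columns=samples)
    return BetaMatrix(platform=mapping.target_platform, values=frame)


def write_beta_tsv(b: BetaMatrix, path: str | Path) -> None:
    """First column ``Probe_ID``, one column per sample, missing as ``NA``."""
    df = b.values.copy()
    df.index.name = "Probe_ID"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_beta_tsv(path: str | Path, platform: str = "unknown") -> BetaMatrix:
    df = pd.read_csv(path, sep="\t", index_col="Probe_ID", na_values=["NA"])
    return BetaMatrix(platform=platform, values=df.astype(float))
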