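"""Signal-intensity frame conversion between platforms.

Raw Infinium readouts are per-probe methylated (M) and unmethylated (U)
fluorescence intensities; their sum tracks local DNA copy number, which is
why harmonized signal frames feed copy-number workflows.  Conversion moves
records onto the target platform's probe IDs along the prefix mapping.
Unlike beta conversion, replicate resolution never averages intensities —
averaging raw signal across differently designed probes would conflate
chemistries — so when several source replicates feed one target probe, the
record with the most significant detection p-value is transferred verbatim.
Signal imputation for absent probes is deliberately unsupported: target
probes with no source feed are simply absent from the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .probe_identity import MappingTable, parse_probe_id

logger = logging.getLogger(__name__)

__all__ = [
    "SignalFrame",
    "convert_signal",
    "total_intensity",
    "read_signal_tsv",
    "write_signal_tsv",
]

_COLUMNS = ["M", "U", "detection_p", "masked"]


@dataclass
class SignalFrame:
    """Per-probe intensity records for one sample.

    ``data`` is a DataFrame indexed by probe full-ID with columns ``M`` and
    ``U`` (nonnegative finite intensities), ``detection_p`` (in [0,1], NaN if
    missing) and ``masked`` (design-issue flag).
    """

    platform: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"signal frame lacks columns {missing}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate probe IDs in signal frame")
        for col in ("M", "U"):
            v = self.data[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{col} intensities must be finite and nonnegative")
        p = self.data["detection_p"].to_numpy(dtype=float)
        finite = p[~np.isnan(p)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("detection p-values must lie in [0, 1]")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


def convert_signal(s: SignalFrame, mapping: MappingTable) -> SignalFrame:
    """Move signal records onto the target platform along the probe mapping.

    One source feed: the record is copied under the target ID.  Several
    feeds: the unmasked record with the smallest detection p-value wins (ties
    break to the lexicographically lowest source ID); if every candidate is
    masked, the least-p masked record is used and stays flagged masked so
    downstream analyses can exclude it.  A source record fanning out to
    several replicate targets is duplicated per target.  Chemistry-mismatched
    transfers (Infinium I record landing on a II design or vice versa, read
    from the ID suffixes) are counted and logged, never altered.
    """
    if s.platform != mapping.source_platform:
        raise ValueError(
            f"signal platform {s.platform!r} != mapping source {mapping.source_platform!r}"
        )
    present = set(s.data.index)
    by_target: dict[str, list[str]] = {}
    for p in mapping.pairs:
        if p.source_id in present:
            by_target.setdefault(p.target_id, []).append(p.source_id)

    rows: list[pd.Series] = []
    index: list[str] = []
    chem_mismatch = 0
    for tgt in sorted(by_target):
        sources = sorted(by_target[tgt])
        if len(sources) == 1:
            chosen = sources[0]
        else:
            cand = s.data.loc[sources]
            unmasked = cand[~cand["masked"].astype(bool)]
            pool = unmasked if len(unmasked) else cand
            p = pool["detection_p"].to_numpy(dtype=float)
            p = np.where(np.isnan(p), np.inf, p)
            chosen = pool.index[int(np.argmin(p))]  # sources sorted: ties -> lowest ID
        rec = s.data.loc[chosen]
        src_chem = parse_probe_id(chosen).suffix
        tgt_chem = parse_probe_id(tgt).suffix
        if (
            src_chem is not None
            and tgt_chem is not None
            and src_chem.chemistry != tgt_chem.chemistry
        ):
            chem_mismatch += 1
        rows.append(rec)
        index.append(tgt)

    if chem_mismatch:
        logger.info(
            "convert_signal: %d records transferred across an Infinium "
            "chemistry mismatch",
            chem_mismatch,
        )
    if rows:
        data = pd.DataFrame(rows)
        data.index = pd.Index(index, name="Probe_ID")
    else:
        data = pd.DataFrame(columns=_COLUMNS, index=pd.Index([], name="Probe_ID"))
    data["masked"] = data["masked"].astype(bool)
    return SignalFrame(platform=mapping.target_platform, data=data)


def total_intensity(s: SignalFrame) -> pd.Series:
    """Per-probe M + U, the copy-number-tracking total signal.

    Masked probes are included (the mask travels with the frame; exclusion is
    the downstream caller's decision).
    """
    return s.data["M"].astype(float) + s.data["U"].astype(float)


def write_signal_tsv(s: SignalFrame, path: str | Path) -> None:
    """Columns ``Probe_ID, M, U, Detection_P, Mask``; missing p as ``NA``."""
    df = pd.DataFrame(
        {
            "M": s.data["M"].astype(float),
            "U": s.data["U"].astype(float),
            "Detection_P": s.data["detection_p"].astype(float),
            "Mask": s.data["masked"].map({True: "TRUE", False: "FALSE"}),
        }
    )
    df.index.name = "Probe_ID"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_signal_tsv(path: str | Path, platform: str = "unknown") -> SignalFrame:
    df = pd.read_csv(path, sep="\t", index_col="Probe_ID", na_values=["NA"])
    data = pd.DataFrame(
        {
            "M": df["M"].astype(float),
            "U": df["U"].astype(float),
            "detection_p": df["Detection_P"].astype(float),
            "masked": df["Mask"].astype(str).str.upper() == "TRUE",
        }
    )
    return SignalFrame(platform=platform, data=data)
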