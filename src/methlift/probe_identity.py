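"""Probe-ID grammar, platform manifests, replicate grouping and ID mapping.

Infinium BeadChips identify each assayed CpG by a "cg number" (e.g.
``cg00000029``).  Newer platforms (EPICv2, MSA) extend the ID with a
four-character design suffix encoding strand orientation, bisulfite-conversion
designator, Infinium chemistry and a replicate index, e.g. ``cg00000029_TC21``.
Probes that share a prefix but differ in suffix are *replicates*: distinct
designs interrogating the same CpG.  Cross-platform harmonization pairs probes
purely by shared prefix; suffix fields are parsed and preserved but never
required to match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ProbeParseError",
    "ProbeSuffix",
    "ProbeID",
    "ManifestRecord",
    "Manifest",
    "MappingPair",
    "MappingTable",
    "parse_probe_id",
    "format_probe_id",
    "replicate_groups",
    "build_id_mapping",
    "read_manifest_tsv",
    "write_manifest_tsv",
    "read_mapping_tsv",
    "write_mapping_tsv",
]


class ProbeParseError(ValueError):
    """Raised when a probe ID string does not match the ID grammar."""


#: Suffix grammar, isolated so other dialects can be registered: one table
#: per field mapping the single character in the rendered suffix to the
#: decoded value.  The default dialect follows the EPICv2/MSA convention:
#: ``_`` separator then [strand][conversion][chemistry][replicate].
SUFFIX_GRAMMAR: dict[str, Mapping[str, object]] = {
    "strand": {"T": "T", "B": "B"},
    "conversion": {"C": "C", "O": "O"},
    "chemistry": {"1": "I", "2": "II"},
    "replicate_index": {str(d): d for d in range(10)},
}

#: Probe-class codes accepted as prefixes (control probes are out of scope).
PROBE_CLASS_CODES: tuple[str, ...] = ("cg", "ch", "rs")

_PREFIX_RE = re.compile(r"^(?P<code>[a-z]+)(?P<digits>\d+)$")
_SUFFIX_RE = re.compile(r"^(?P<strand>[TB])(?P<conv>[CO])(?P<chem>[12])(?P<rep>[0-9])$")

_CHEM_TO_CODE = {"I": "1", "II": "2"}


@dataclass(frozen=True)
class ProbeSuffix:
    """Design suffix of a suffixed-era probe ID.

    strand: targeted DNA strand, Top or Bottom.
    conversion: bisulfite-conversion designator (parsed, never interpreted).
    chemistry: Infinium bead chemistry, "I" or "II".
    replicate_index: distinguishes replicate designs sharing one prefix.
    """

    strand: str
    conversion: str
    chemistry: str
    replicate_index: int

    def __post_init__(self) -> None:
        if self.strand not in ("T", "B"):
            raise ProbeParseError(f"bad strand designator {self.strand!r}")
        if self.conversion not in ("C", "O"):
            raise ProbeParseError(f"bad conversion designator {self.conversion!r}")
        if self.chemistry not in ("I", "II"):
            raise ProbeParseError(f"bad chemistry designator {self.chemistry!r}")
        if not 0 <= self.replicate_index <= 9:
            raise ProbeParseError(
                f"replicate index {self.replicate_index!r} outside single-digit range"
            )

    def render(self) -> str:
        return (
            f"{self.strand}{self.conversion}"
            f"{_CHEM_TO_CODE[self.chemistry]}{self.replicate_index}"
        )


@dataclass(frozen=True)
class ProbeID:
    """A parsed Infinium probe identifier: prefix plus optional design suffix."""

    prefix: str
    suffix: ProbeSuffix | None = None

    @property
    def full_id(self) -> str:
        if self.suffix is None:
            return self.prefix
        return f"{self.prefix}_{self.suffix.render()}"

    def is_replicate_of(self, other: "ProbeID") -> bool:
        """True iff both target the same CpG through distinct designs."""
        return self.prefix == other.prefix and self.full_id != other.full_id

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.full_id


def parse_probe_id(raw: str) -> ProbeID:
    """Parse a probe ID string into its structured form.

    Accepts the legacy pattern (class code + digits, e.g. ``cg00000029``) and
    the suffixed pattern (legacy + ``_`` + 4-character suffix, e.g.
    ``cg00000029_TC21``).  ``format_probe_id(parse_probe_id(s)) == s`` for any
    accepted ``s``.

    Raises
    ------
    ProbeParseError
        If the string is empty, the class code is unknown, or the suffix
        violates the grammar; the message names the offending segment.
    """
    if not raw:
        raise ProbeParseError("empty probe ID")
    prefix_part, sep, suffix_part = raw.partition("_")
    m = _PREFIX_RE.match(prefix_part)
    if m is None or m.group("code") not in PROBE_CLASS_CODES:
        raise ProbeParseError(
            f"probe ID {raw!r}: prefix {prefix_part!r} does not match "
            f"<class code in {PROBE_CLASS_CODES}><digits>"
        )
    if not sep:
        return ProbeID(prefix=prefix_part)
    sm = _SUFFIX_RE.match(suffix_part)
    if sm is None:
        raise ProbeParseError(
            f"probe ID {raw!r}: suffix {suffix_part!r} does not match "
            "[TB][CO][12][0-9]"
        )
    suffix = ProbeSuffix(
        strand=sm.group("strand"),
        conversion=sm.group("conv"),
        chemistry=SUFFIX_GRAMMAR["chemistry"][sm.group("chem")],  # type: ignore[arg-type]
        replicate_index=int(sm.group("rep")),
    )
    return ProbeID(prefix=prefix_part, suffix=suffix)


def format_probe_id(p: ProbeID) -> str:
    """Render a ProbeID back to its string form (inverse of parse)."""
    return p.full_id


@dataclass(frozen=True)
class ManifestRecord:
    probe_id: ProbeID
    chemistry: str = "II"
    masked_by_design: bool = False

    def __post_init__(self) -> None:
        if self.chemistry not in ("I", "II"):
            raise ValueError(f"chemistry must be 'I' or 'II', got {self.chemistry!r}")
        sfx = self.probe_id.suffix
        if sfx is not None and sfx.chemistry != self.chemistry:
            raise ValueError(
                f"{self.probe_id.full_id}: manifest chemistry {self.chemistry!r} "
                f"contradicts suffix chemistry {sfx.chemistry!r}"
            )


@dataclass
class Manifest:
    """Per-platform probe catalog."""

    platform: str
    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            fid = rec.probe_id.full_id
            if fid in seen:
                raise ValueError(f"duplicate probe ID {fid!r} in manifest {self.platform!r}")
            seen.add(fid)

    @property
    def full_ids(self) -> list[str]:
        return [rec.probe_id.full_id for rec in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, full_id: str) -> bool:
        return any(rec.probe_id.full_id == full_id for rec in self.records)


def replicate_groups(m: Manifest) -> dict[str, list[str]]:
    """Group a manifest's probes by shared cg-number prefix.

    Every full ID appears in exactly one group; singleton groups are kept, so
    the group sizes sum to the manifest size.
    """
    groups: dict[str, list[str]] = {}
    for rec in m.records:
        groups.setdefault(rec.probe_id.prefix, []).append(rec.probe_id.full_id)
    return groups


@dataclass(frozen=True)
class MappingPair:
    source_id: str
    target_id: str
    high_confidence: bool = True


@dataclass
class MappingTable:
    """Prefix-matched probe pairs from a source to a target platform.

    A prefix carried by j source probes and k target probes contributes all
    j x k pairs.  ``high_confidence`` starts true everywhere and is refined by
    the empirical bias filter.
    """

    source_platform: str
    target_platform: str
    pairs: list[MappingPair] = field(default_factory=list)

    def validate(
        self,
        source: Manifest | None = None,
        target: Manifest | None = None,
    ) -> None:
        seen: set[tuple[str, str]] = set()
        for p in self.pairs:
            key = (p.source_id, p.target_id)
            if key in seen:
                raise ValueError(f"duplicate mapping pair {key}")
            seen.add(key)
            if parse_probe_id(p.source_id).prefix != parse_probe_id(p.target_id).prefix:
                raise ValueError(f"pair {key} does not share a prefix")
        if source is not None:
            known = set(source.full_ids)
            missing = {p.source_id for p in self.pairs} - known
            if missing:
                raise ValueError(f"source IDs absent from manifest: {sorted(missing)[:5]}")
        if target is not None:
            known = set(target.full_ids)
            missing = {p.target_id for p in self.pairs} - known
            if missing:
                raise ValueError(f"target IDs absent from manifest: {sorted(missing)[:5]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Source_ID": [p.source_id for p in self.pairs],
                "Target_ID": [p.target_id for p in self.pairs],
                "High_Confidence": [p.high_confidence for p in self.pairs],
            }
        )

    def __len__(self) -> int:
        return len(self.pairs)


def build_id_mapping(source: Manifest, target: Manifest) -> MappingTable:
    """Enumerate all prefix-matched (source, target) probe pairs.

    Source probes whose prefix has no counterpart on the target platform are
    absent from the result: they are candidates for reference-based imputation
    downstream.  All pairs start with ``high_confidence=True``.
    """
    tgt_by_prefix = replicate_groups(target)
    pairs: list[MappingPair] = []
    for rec in source.records:
        prefix = rec.probe_id.prefix
        for tgt_id in tgt_by_prefix.get(prefix, ()):
            pairs.append(MappingPair(rec.probe_id.full_id, tgt_id, True))
    return MappingTable(
        source_platform=source.platform,
        target_platform=target.platform,
        pairs=pairs,
    )


# ---------------------------------------------------------------------------
# TSV dialects: Probe_ID / Chemistry / Mask for manifests,
# Source_ID / Target_ID / High_Confidence for mappings.

def write_manifest_tsv(m: Manifest, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "Probe_ID": [r.probe_id.full_id for r in m.records],
            "Chemistry": [r.chemistry for r in m.records],
            "Mask": ["TRUE" if r.masked_by_design else "FALSE" for r in m.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_manifest_tsv(path: str | Path, platform: str | None = None) -> Manifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = [
        ManifestRecord(
            probe_id=parse_probe_id(row.Probe_ID),
            chemistry=row.Chemistry,
            masked_by_design=row.Mask.upper() == "TRUE",
        )
        for row in df.itertuples(index=False)
    ]
    return Manifest(platform=platform or str(Path(path).stem), records=records)


def write_mapping_tsv(mapping: MappingTable, path: str | Path) -> None:
    df = mapping.to_frame()
    df["High_Confidence"] = df["High_Confidence"].map({True: "TRUE", False: "FALSE"})
    df.to_csv(path, sep="\t", index=False)


def read_mapping_tsv(
    path: str | Path, source_platform: str = "source", target_platform: str = "target"
) -> MappingTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    pairs = [
        MappingPair(row.Source_ID, row.Target_ID, row.High_Confidence.upper() == "TRUE")
        for row in df.itertuples(index=False)
    ]
    return MappingTable(source_platform, target_platform, pairs)
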