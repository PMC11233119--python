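"""Parse suffixed probe IDs and build a cross-platform probe mapping.

EPICv2-style IDs keep the legacy cg number as a prefix and append a
4-character design suffix (strand, conversion, chemistry, replicate index).
Mapping between platforms pairs probes purely by shared prefix, so one
legacy probe can fan out to several replicate designs.
"""

from methlift import (
    Manifest,
    ManifestRecord,
    build_id_mapping,
    parse_probe_id,
    replicate_groups,
)

for raw in ("cg00000029", "cg00000029_TC21", "ch00000108_BO11"):
    p = parse_probe_id(raw)
    print(f"{raw:24s} prefix={p.prefix:12s} suffix={p.suffix}")

legacy = Manifest(
    "HM450-like",
    [ManifestRecord(parse_probe_id(i)) for i in ("cg00000029", "cg00000108")],
)
suffixed = Manifest(
    "EPICv2-like",
    [
        ManifestRecord(parse_probe_id(i), chemistry=c)
        for i, c in (
            ("cg00000029_TC21", "II"),
            ("cg00000029_BC22", "II"),
            ("cg00000109_TC11", "I"),
        )
    ],
)
print("\nreplicate groups on the suffixed platform:", replicate_groups(suffixed))

mapping = build_id_mapping(legacy, suffixed)
print(f"\nmapping {mapping.source_platform} -> {mapping.target_platform}:")
for pair in mapping.pairs:
    print(f"  {pair.source_id} -> {pair.target_id}")
print(
    "cg00000029 feeds both replicate designs; cg00000108 has no prefix match\n"
    "on the target, so it is absent from the mapping (an imputation candidate)."
)
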