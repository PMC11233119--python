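"""Synthetic fixtures with known ground truth.

Everything the other modules consume — platform manifest pairs, tissue-
structured beta cohorts with a matching imputation reference, paired
same-sample experiments carrying an injected platform bias — can be
generated here deterministically from a seed.  The generators emulate the
data regime the method is validated in (a legacy platform without ID
suffixes versus a newer one with replicate designs; tissue identity as the
dominant source of methylation variation; platform bias as an operational
beta-offset on a probe subset) while staying small enough for desk-scale
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beta_liftover import BetaMatrix
from .bias_filter import PairedExperiment
from .imputation import ImputationReference
from .probe_identity import (
    Manifest,
    ManifestRecord,
    MappingTable,
    ProbeID,
    ProbeSuffix,
    build_id_mapping,
)
from .signal_liftover import SignalFrame

__all__ = [
    "SimulationConfig",
    "make_platform_pair",
    "simulate_cohort",
    "simulate_paired_experiments",
    "simulate_signal_frame",
    "true_tissue_profiles",
]

# Suffix designs cycled through when a prefix carries several replicates;
# the replicate index makes IDs unique even after the cycle wraps.
_REPLICATE_DESIGNS = [
    ("T", "C", "II"),
    ("B", "C", "II"),
    ("T", "O", "I"),
    ("B", "O", "I"),
    ("T", "C", "I"),
    ("B", "C", "I"),
    ("T", "O", "II"),
    ("B", "O", "II"),
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic data regime.

    seed: base seed; every generator is bit-reproducible given (seed, config).
    n_prefixes: number of distinct cg-number prefixes across both platforms.
    frac_shared: fraction of prefixes present on both platforms; the rest are
        split evenly into platform-specific sets.
    replicate_distribution: replicate-count -> probability on the suffixed
        platform (the legacy platform always has one probe per prefix).
    n_tissues / tissue_separation: number of tissue median profiles and the
        minimum pairwise mean absolute deviation enforced between them.
    noise_sd: per-cell Gaussian noise on the beta scale, clipped to [0, 1].
    bias_probes / bias_magnitude: fraction of mapped target probes receiving a
        fixed platform offset in paired experiments, and its size.
    mask_fraction: fraction of manifest probes flagged masked-by-design.
    reference_draws: per-tissue sample count behind the reference summaries.
    """

    seed: int = 0
    n_prefixes: int = 300
    frac_shared: float = 0.8
    replicate_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    n_tissues: int = 5
    tissue_separation: float = 0.1
    noise_sd: float = 0.02
    bias_probes: float = 0.1
    bias_magnitude: float = 0.2
    mask_fraction: float = 0.02
    reference_draws: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_shared <= 1.0:
            raise ValueError("frac_shared must lie in [0, 1]")
        if not 0.0 <= self.bias_probes <= 1.0:
            raise ValueError("bias_probes must lie in [0, 1]")
        if not 0.0 <= self.mask_fraction <= 1.0:
            raise ValueError("mask_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        total = sum(self.replicate_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"replicate probabilities must sum to 1, got {total}")
        if any(k < 1 or k > 9 for k in self.replicate_distribution):
            raise ValueError("replicate counts must lie in 1..9")
        if self.n_prefixes < 1 or self.n_tissues < 1:
            raise ValueError("n_prefixes and n_tissues must be positive")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # Independent, reproducible stream per generator.
    return np.random.default_rng([cfg.seed, stream])


def _draw_prefixes(rng: np.random.Generator, n: int) -> list[str]:
    nums = rng.choice(10**8, size=n, replace=False)
    return [f"cg{int(v):08d}" for v in nums]


def make_platform_pair(
    cfg: SimulationConfig,
    legacy_platform: str = "LEGACY",
    suffixed_platform: str = "SUFFIXED",
) -> tuple[Manifest, Manifest, MappingTable]:
    """A legacy-style and a suffixed-style manifest plus the true mapping.

    Shared prefixes appear on both platforms; the suffixed platform draws its
    replicate count per prefix from ``cfg.replicate_distribution``.  The
    returned mapping enumerates every prefix-matched pair (the ground truth
    that :func:`methlift.probe_identity.build_id_mapping` should recover).
    """
    rng = _rng(cfg, 1)
    prefixes = _draw_prefixes(rng, cfg.n_prefixes)
    n_shared = int(round(cfg.frac_shared * cfg.n_prefixes))
    shared = prefixes[:n_shared]
    rest = prefixes[n_shared:]
    legacy_only = rest[: len(rest) // 2]
    suffixed_only = rest[len(rest) // 2 :]

    counts = sorted(cfg.replicate_distribution)
    probs = [cfg.replicate_distribution[k] for k in counts]

    legacy_records = [
        ManifestRecord(
            probe_id=ProbeID(prefix=p),
            chemistry="II",
            masked_by_design=bool(rng.random() < cfg.mask_fraction),
        )
        for p in shared + legacy_only
    ]

    suffixed_records: list[ManifestRecord] = []
    for p in shared + suffixed_only:
        k = int(rng.choice(counts, p=probs))
        for i in range(k):
            strand, conv, chem = _REPLICATE_DESIGNS[i % len(_REPLICATE_DESIGNS)]
            sfx = ProbeSuffix(
                strand=strand, conversion=conv, chemistry=chem, replicate_index=i + 1
            )
            suffixed_records.append(
                ManifestRecord(
                    probe_id=ProbeID(prefix=p, suffix=sfx),
                    chemistry=chem,
                    masked_by_design=bool(rng.random() < cfg.mask_fraction),
                )
            )

    legacy = Manifest(platform=legacy_platform, records=legacy_records)
    suffixed = Manifest(platform=suffixed_platform, records=suffixed_records)
    truth = build_id_mapping(legacy, suffixed)
    return legacy, suffixed, truth


def _tissue_profiles(
    rng: np.random.Generator, cfg: SimulationConfig, probes: list[str]
) -> pd.DataFrame:
    """Bimodal tissue median profiles with pairwise MAD >= tissue_separation.

    Values are drawn away from 0 and 1 (in [0.05, 0.95]) so that clipped
    Gaussian noise stays symmetric around the profile and reference medians
    estimate it without boundary bias.  Independent bimodal profiles are far
    apart with overwhelming probability; the redraw loop enforces the bound
    deterministically.
    """
    n_probes = len(probes)
    for _ in range(100):
        low = rng.uniform(0.05, 0.25, size=(cfg.n_tissues, n_probes))
        high = rng.uniform(0.75, 0.95, size=(cfg.n_tissues, n_probes))
        pick_high = rng.random((cfg.n_tissues, n_probes)) < 0.5
        prof = np.where(pick_high, high, low)
        ok = all(
            np.abs(prof[i] - prof[j]).mean() >= cfg.tissue_separation
            for i in range(cfg.n_tissues)
            for j in range(i + 1, cfg.n_tissues)
        )
        if ok:
            tissues = [f"tissue{t + 1}" for t in range(cfg.n_tissues)]
            return pd.DataFrame(prof, index=tissues, columns=probes)
    raise RuntimeError(
        "could not generate tissue profiles with the requested separation"
    )


def true_tissue_profiles(cfg: SimulationConfig, manifest: Manifest) -> pd.DataFrame:
    """The generating tissue x probe median profiles behind simulate_cohort.

    Drawn from the same stream before any noise is consumed, so the returned
    profiles are exactly those a :func:`simulate_cohort` call with the same
    config samples around — the ground truth for recovery benchmarks.
    """
    return _tissue_profiles(_rng(cfg, 2), cfg, manifest.full_ids)


def simulate_cohort(
    cfg: SimulationConfig,
    manifest: Manifest,
    n_samples_per_tissue: int,
) -> tuple[BetaMatrix, list[str], ImputationReference]:
    """Cohort of samples drawn around tissue profiles, plus a reference panel.

    Each sample is its tissue's median profile plus clipped Gaussian noise.
    The reference medians/SDs come from an independent draw of
    ``cfg.reference_draws`` samples per tissue, so the reference is an
    estimate of the generating profile, exactly as an empirical repository
    would be (and exactly equal to it when ``noise_sd`` is zero).
    """
    rng = _rng(cfg, 2)
    probes = manifest.full_ids
    profiles = _tissue_profiles(rng, cfg, probes)
    tissues = list(profiles.index)

    labels: list[str] = []
    columns: dict[str, np.ndarray] = {}
    for t in tissues:
        base = profiles.loc[t].to_numpy()
        for i in range(n_samples_per_tissue):
            noise = rng.normal(0.0, cfg.noise_sd, size=len(probes)) if cfg.noise_sd else 0.0
            columns[f"{t}_s{i + 1}"] = np.clip(base + noise, 0.0, 1.0)
            labels.append(t)
    betas = BetaMatrix(
        platform=manifest.platform,
        values=pd.DataFrame(columns, index=pd.Index(probes, name="Probe_ID")),
    )

    med = np.empty((len(tissues), len(probes)))
    sd = np.empty_like(med)
    for ti, t in enumerate(tissues):
        base = profiles.loc[t].to_numpy()
        if cfg.noise_sd:
            draws = np.clip(
                base[None, :]
                + rng.normal(0.0, cfg.noise_sd, size=(cfg.reference_draws, len(probes))),
                0.0,
                1.0,
            )
            med[ti] = np.median(draws, axis=0)
            sd[ti] = draws.std(axis=0)
        else:
            # all draws coincide with the profile: summaries are exact
            med[ti] = base
            sd[ti] = 0.0
    ref = ImputationReference(
        platform=manifest.platform,
        median=pd.DataFrame(med, index=tissues, columns=probes),
        sd=pd.DataFrame(sd, index=tissues, columns=probes),
        n_samples={t: cfg.reference_draws for t in tissues},
    )
    return betas, labels, ref


def simulate_paired_experiments(
    cfg: SimulationConfig,
    mapping: MappingTable,
    n_experiments: int,
) -> tuple[list[PairedExperiment], set[tuple[str, str]]]:
    """Paired two-platform experiments with a known platform-biased subset.

    A fixed fraction of mapped target probes receives a ``bias_magnitude``
    offset on the target side in *every* experiment (directed toward the
    interior of [0, 1] so it never saturates); all other probes differ only
    by measurement noise.  Returns the experiments and the ground-truth set
    of biased (source_id, target_id) pairs.
    """
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    rng = _rng(cfg, 3)
    from .probe_identity import parse_probe_id

    pair_list = [(p.source_id, p.target_id) for p in mapping.pairs]
    targets = sorted({t for _, t in pair_list})
    n_biased = int(round(cfg.bias_probes * len(targets)))
    biased_targets = set(
        rng.choice(targets, size=n_biased, replace=False)
    ) if n_biased else set()
    biased_pairs = {(s, t) for s, t in pair_list if t in biased_targets}

    prefixes = sorted({parse_probe_id(s).prefix for s, _ in pair_list})
    experiments: list[PairedExperiment] = []
    for e in range(n_experiments):
        truth = dict(zip(prefixes, rng.uniform(0.05, 0.95, size=len(prefixes))))
        src: dict[str, float] = {}
        tgt: dict[str, float] = {}
        for s, t in pair_list:
            base = truth[parse_probe_id(s).prefix]
            s_noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd else 0.0
            t_noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd else 0.0
            offset = 0.0
            if t in biased_targets:
                offset = -cfg.bias_magnitude if base > 0.5 else cfg.bias_magnitude
            src[s] = float(np.clip(base + s_noise, 0.0, 1.0))
            tgt[t] = float(np.clip(base + offset + t_noise, 0.0, 1.0))
        experiments.append(
            PairedExperiment(label=f"pair{e + 1}", source_betas=src, target_betas=tgt)
        )
    return experiments, biased_pairs


def simulate_signal_frame(
    cfg: SimulationConfig,
    manifest: Manifest,
    mean_total: float = 4000.0,
) -> SignalFrame:
    """One sample's signal frame: intensities, detection p-values, masks.

    Total intensity is drawn around ``mean_total`` and split between M and U
    by a bimodal methylation fraction; detection p-values are small for most
    probes with an occasional poor detection.
    """
    rng = _rng(cfg, 4)
    n = len(manifest)
    total = rng.gamma(shape=20.0, scale=mean_total / 20.0, size=n)
    frac = np.where(rng.random(n) < 0.5, rng.uniform(0.0, 0.2, n), rng.uniform(0.8, 1.0, n))
    m = total * frac
    u = total - m
    detp = np.where(rng.random(n) < 0.95, rng.uniform(0.0, 0.01, n), rng.uniform(0.05, 1.0, n))
    masked = np.array([r.masked_by_design for r in manifest.records])
    data = pd.DataFrame(
        {"M": m, "U": u, "detection_p": detp, "masked": masked},
        index=pd.Index(manifest.full_ids, name="Probe_ID"),
    )
    return SignalFrame(platform=manifest.platform, data=data)
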