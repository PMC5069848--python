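"""Structured synthetic datasets with known ground truth.

Genotypes follow the Balding-Nichols construction: ancestral allele
frequencies are drawn from a flat Dirichlet per locus and each group's
frequencies from a Dirichlet centred on them with concentration
``p * (1 - Fst) / Fst``, which matches an island-model Fst target
analytically and runs in milliseconds.  A stepping-stone variant
(``structure_model="cline"``) chains the group draws along the depth order
so that divergence grows monotonically with depth separation, the regime
the Mantel stage is meant to detect.

Traits are multiplicative allometries ``a * SL^b * exp(group shift + noise)``
on a lognormal standard length, with the group shifts carrying the
between-group variance (exactly: the shifts are normalized so their sample
variance equals ``sigma2_between``, making the simulated truth the stated
truth rather than a draw around it).  Buoyancy is generated through the
weight pair so the in-air/in-water arithmetic recovers the intended cline,
and the early-growth column satisfies omega = Lmax * K identically.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    GenotypeTable,
    LINEAR_TRAITS,
    depth_category_of,
    stratum_of,
    validate_sample_frame,
)

ISLE_ROYALE = (-88.83, 48.0)  # lon, lat of the sampling region


@dataclass
class TraitSpec:
    """Ground-truth description of one simulated trait.

    ``sigma2_between``/``sigma2_within`` are variances of the group-mean
    shifts and of the residual, on the (natural-log) residual scale for
    allometric traits and on the raw scale for additive ones
    (``allometric_exponent = 0`` together with ``additive=True`` semantics:
    PC scores and buoyancy are additive).  ``depth_trend`` imposes a
    monotone arrangement of the group means along the depth order;
    ``variance_trend`` scales the within-group variance monotonically.
    """

    name: str
    sigma2_between: float = 0.0
    sigma2_within: float = 0.01
    heritability_h2: float = 1.0
    allometric_exponent: float = 1.0
    depth_trend: str = "none"
    variance_trend: str = "none"
    additive: bool = False

    def __post_init__(self) -> None:
        if self.sigma2_between < 0 or self.sigma2_within < 0:
            raise ValueError("variances must be >= 0")
        if not 0 < self.heritability_h2 <= 1:
            raise ValueError("heritability must lie in (0, 1]")
        for attr in ("depth_trend", "variance_trend"):
            if getattr(self, attr) not in ("none", "increasing", "decreasing"):
                raise ValueError(f"{attr} must be none/increasing/decreasing")


@dataclass
class SynthConfig:
    """Parameters of one synthetic dataset.

    Defaults emulate the study system: 18 microsatellite loci with 3-20
    alleles each (mean 11.5), three depth-stratum groups of the genotyped
    sample sizes, and weak differentiation.
    """

    n_groups: int = 3
    group_sizes: tuple[int, ...] = (83, 217, 71)
    n_loci: int = 18
    alleles_per_locus: int | tuple[int, int] = (3, 20)
    target_fst: float = 0.005
    depth_per_group: tuple[float, ...] = (40.0, 75.0, 120.0)
    trait_specs: list[TraitSpec] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0
    structure_model: str = "island"
    n_sites: int = 20
    buoyancy_base_pct: float = 85.0
    mean_sl_mm: float = 550.0
    #: relative shallow-to-deep decline in asymptotic length and early
    #: growth rate (0 = no life-history cline)
    lmax_decline: float = 0.12
    growth_decline: float = 0.20

    def __post_init__(self) -> None:
        if len(self.group_sizes) != self.n_groups:
            raise ValueError("group_sizes must have n_groups entries")
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("every group needs >= 2 individuals")
        if not 0 <= self.target_fst <= 0.5:
            raise ValueError("target_fst must lie in [0, 0.5]")
        if not 0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5]")
        if len(self.depth_per_group) != self.n_groups:
            raise ValueError("depth_per_group must have n_groups entries")
        if self.structure_model not in ("island", "cline"):
            raise ValueError("structure_model must be 'island' or 'cline'")


def _group_frequencies(
    p: np.ndarray, fst: float, n_groups: int, model: str, rng: np.random.Generator
) -> np.ndarray:
    """Per-group allele frequencies for one locus under the chosen model."""
    if fst == 0:
        return np.tile(p, (n_groups, 1))
    conc = p * (1.0 - fst) / fst
    if model == "island":
        return rng.dirichlet(conc, size=n_groups)
    freqs = [rng.dirichlet(conc)]
    for _ in range(1, n_groups):
        prev = np.clip(freqs[-1], 1e-9, None)
        prev = prev / prev.sum()
        freqs.append(rng.dirichlet(prev * (1.0 - fst) / fst))
    return np.stack(freqs)


def simulate_genotypes(config: SynthConfig) -> tuple[GenotypeTable, pd.DataFrame]:
    """Draw genotypes and matching per-individual metadata.

    One RNG stream is seeded from ``config.seed`` and split per locus, so
    changing the locus count leaves earlier loci untouched.  Identical
    configs produce byte-identical GenePop exports.
    """
    ss = np.random.SeedSequence(config.seed)
    meta_rng = np.random.default_rng(ss.spawn(1)[0])
    locus_rngs = [np.random.default_rng(s) for s in ss.spawn(config.n_loci + 1)[1:]]

    n_total = int(sum(config.group_sizes))
    group_of = np.repeat(np.arange(config.n_groups), config.group_sizes)
    ids = [f"ind{i + 1:04d}" for i in range(n_total)]
    locus_names = [f"Loc{j + 1:02d}" for j in range(config.n_loci)]

    if isinstance(config.alleles_per_locus, int):
        k_per_locus = [config.alleles_per_locus] * config.n_loci
    else:
        lo, hi = config.alleles_per_locus
        k_per_locus = [int(r.integers(lo, hi + 1)) for r in locus_rngs]

    calls = np.zeros((n_total, config.n_loci, 2), dtype=np.int32)
    for j, (k, rng) in enumerate(zip(k_per_locus, locus_rngs)):
        p = rng.dirichlet(np.ones(k))
        freqs = _group_frequencies(
            p, config.target_fst, config.n_groups, config.structure_model, rng
        )
        for g in range(config.n_groups):
            rows = np.flatnonzero(group_of == g)
            draws = rng.choice(k, size=(len(rows), 2), p=freqs[g]) + 1
            calls[rows, j, :] = draws
        if config.missing_rate > 0:
            miss = rng.random(n_total) < config.missing_rate
            calls[miss, j, :] = 0

    gt = GenotypeTable(
        ids,
        locus_names,
        calls,
        [f"stratum{g + 1}" for g in group_of],
    )
    frame = _simulate_frame(config, group_of, ids, meta_rng)
    return gt, frame


_CATEGORY_CHOICES = {
    "<50 m": [40.0],
    "50-100 m": [50.0, 80.0, 90.0, 100.0],
    ">100 m": [125.0],
}


def _simulate_frame(
    config: SynthConfig,
    group_of: np.ndarray,
    ids: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Metadata emulating the sampling design: ecotype assigned independently
    of genotype (roughly the observed relative abundances), three zones,
    twenty sites around the island, and capture depths drawn from the six
    net-depth categories consistent with each group's stratum."""
    n = len(ids)
    ecotype = rng.choice(
        ["siscowet", "lean", "humper", "redfin"],
        size=n,
        p=[0.539, 0.239, 0.121, 0.101],
    )
    zone = rng.choice(["Zone1", "Zone2", "Zone3"], size=n)
    site = rng.integers(0, config.n_sites, size=n)
    angles = np.linspace(0, 2 * np.pi, config.n_sites, endpoint=False)
    lon = ISLE_ROYALE[0] + 0.35 * np.cos(angles)
    lat = ISLE_ROYALE[1] + 0.20 * np.sin(angles)
    depth = np.empty(n)
    for i in range(n):
        stratum = stratum_of(config.depth_per_group[group_of[i]])
        depth[i] = rng.choice(_CATEGORY_CHOICES[stratum])
    frame = pd.DataFrame(
        {
            "individual_id": ids,
            "ecotype": ecotype,
            "zone": zone,
            "capture_depth_m": depth,
            "site_id": [f"site{s + 1:02d}" for s in site],
            "lon": lon[site],
            "lat": lat[site],
            "group": [f"stratum{g + 1}" for g in group_of],
        }
    )
    return validate_sample_frame(frame)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def _group_offsets(
    spec: TraitSpec,
    depth_order: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Group-mean shifts with sample variance exactly sigma2_between.

    Under a depth trend the shifts are evenly spaced along the depth order;
    otherwise they are Gaussian draws.  Either way they are centred and
    rescaled so their ddof-1 variance equals ``sigma2_between``, making the
    generator's truth exact rather than a random draw around the target.
    """
    k = len(depth_order)
    if spec.sigma2_between == 0:
        return np.zeros(k)
    if spec.depth_trend == "none":
        raw = rng.standard_normal(k)
        while np.ptp(raw) < 1e-9:  # pragma: no cover - measure-zero guard
            raw = rng.standard_normal(k)
    else:
        ranks = np.empty(k)
        ranks[depth_order] = np.arange(k, dtype=float)
        raw = ranks if spec.depth_trend == "increasing" else -ranks
    raw = raw - raw.mean()
    return raw * np.sqrt(spec.sigma2_between / raw.var(ddof=1))


def _variance_scale(spec: TraitSpec, depth_order: np.ndarray) -> np.ndarray:
    """Per-group within-variance multipliers implementing variance_trend."""
    k = len(depth_order)
    if spec.variance_trend == "none":
        return np.ones(k)
    ladder = np.geomspace(1.0, 4.0, k)
    if spec.variance_trend == "decreasing":
        ladder = ladder[::-1]
    scale = np.empty(k)
    scale[depth_order] = ladder
    return scale


#: Baseline allometric intercepts (mm at SL = 1 mm is meaningless, so these
#: are chosen to land the traits in realistic ranges at SL ~ 550 mm).
_TRAIT_INTERCEPTS = {name: 0.15 for name in LINEAR_TRAITS}


def simulate_traits(config: SynthConfig, frame: pd.DataFrame) -> pd.DataFrame:
    """Trait table matching ``frame``'s individuals and groups.

    Standard length is lognormal; each allometric trait is
    ``a * SL^b * exp(delta_group + e)``; additive traits (PC scores,
    buoyancy) are ``delta_group + e`` on their natural scale.  Buoyancy is
    realized through weight-in-air/weight-in-water so the buoyancy formula
    recovers the simulated cline; life-history columns satisfy
    omega = Lmax * K exactly.
    """
    if "group" not in frame.columns:
        raise ValueError("frame must carry the simulation 'group' column")
    groups = sorted(frame["group"].unique())
    if len(groups) != config.n_groups:
        raise ValueError("frame groups do not match config.n_groups")
    depths = np.asarray(config.depth_per_group, dtype=float)
    order = np.argsort(depths, kind="stable")
    for spec in config.trait_specs:
        if spec.depth_trend != "none" and len(np.unique(depths)) != len(depths):
            raise ValueError(
                f"trait {spec.name!r} requests a depth trend but "
                "depth_per_group is not strictly ordered"
            )
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 917)))
    g_idx = frame["group"].map({g: i for i, g in enumerate(groups)}).to_numpy()
    n = len(frame)

    sl = config.mean_sl_mm * np.exp(rng.normal(0.0, 0.12, size=n))
    out = pd.DataFrame({"individual_id": frame["individual_id"].to_numpy()})
    out["SL_mm"] = sl

    buoy_spec = None
    for spec in config.trait_specs:
        offsets = _group_offsets(spec, order, rng)
        wvar = spec.sigma2_within * _variance_scale(spec, order)
        noise = rng.normal(0.0, 1.0, size=n) * np.sqrt(wvar[g_idx])
        shift = offsets[g_idx] + noise
        if spec.name.lower() == "buoyancy":
            buoy_spec = (spec, shift)
            continue
        if spec.additive or spec.allometric_exponent == 0:
            out[spec.name] = shift
        else:
            a = _TRAIT_INTERCEPTS.get(spec.name, 0.15)
            out[spec.name] = (
                a * sl**spec.allometric_exponent * np.exp(shift)
            )

    # Weights: weight in air is a cubic allometry of SL; weight in water is
    # derived from the buoyancy percentage so the formula inverts exactly.
    weight_air = 1.1e-5 * sl**3.0 * np.exp(rng.normal(0.0, 0.05, size=n))
    buoyancy = np.full(n, config.buoyancy_base_pct)
    if buoy_spec is not None:
        buoyancy = config.buoyancy_base_pct + buoy_spec[1]
    out["weight_air_g"] = weight_air
    out["weight_water_g"] = weight_air * (1.0 - buoyancy / 100.0)
    out["buoyancy_pct"] = buoyancy

    # Life history: early growth declines with depth (deeper fish grow more
    # slowly), asymptotic length mildly so; omega is the exact product.
    rank = np.empty(config.n_groups)
    rank[order] = np.linspace(1.0, 0.0, config.n_groups)
    lmax = 900.0 * (
        1.0 - config.lmax_decline * (1.0 - rank[g_idx])
    ) * np.exp(rng.normal(0.0, 0.05, size=n))
    k_growth = 0.20 * (
        1.0 - config.growth_decline * (1.0 - rank[g_idx])
    ) * np.exp(rng.normal(0.0, 0.08, size=n))
    out["Lmax_mm"] = lmax
    out["K_per_yr"] = k_growth
    out["omega_mm_per_yr"] = lmax * k_growth
    out["t0_yr"] = rng.normal(0.35, 0.05, size=n)
    out["L0_mm"] = rng.normal(21.7, 1.0, size=n)
    return out


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

def available_scenarios() -> list[str]:
    root = importlib.resources.files("depthcline") / "scenarios"
    return sorted(p.stem for p in root.iterdir() if p.suffix == ".yaml")


def load_scenario(name_or_path: str, seed: int | None = None) -> SynthConfig:
    """Load a named preset (neutral, divergent_by_depth, stabilizing) or a
    YAML file path into a SynthConfig; ``seed`` overrides the file's seed."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        res = importlib.resources.files("depthcline") / "scenarios" / (
            f"{name_or_path}.yaml"
        )
        if not res.is_file():
            raise ValueError(
                f"unknown scenario {name_or_path!r}; "
                f"available: {available_scenarios()}"
            )
        text = res.read_text()
    raw = yaml.safe_load(text)
    traits = [TraitSpec(**t) for t in raw.pop("trait_specs", [])]
    raw.pop("name", None)
    for key in ("group_sizes", "depth_per_group", "alleles_per_locus"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = SynthConfig(trait_specs=traits, **raw)
    if seed is not None:
        cfg.seed = seed
    return cfg


def export_dataset(
    config: SynthConfig, outdir: str | Path
) -> tuple[Path, Path, Path]:
    """Simulate and write GenePop + metadata CSV + trait CSV to ``outdir``."""
    from .io_formats import write_genepop

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gt, frame = simulate_genotypes(config)
    traits = simulate_traits(config, frame)
    gen = outdir / "genotypes.gen"
    meta = outdir / "metadata.csv"
    tr = outdir / "traits.csv"
    write_genepop(gt, gen, title=f"depthcline synthetic seed={config.seed}")
    frame.to_csv(meta, index=False)
    traits.to_csv(tr, index=False)
    return gen, meta, tr
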