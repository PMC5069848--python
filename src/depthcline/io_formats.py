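"""Input/output for the formats the pipeline touches.

Genotypes travel as GenePop text (the interchange dialect of the classical
microsatellite toolchain), per-individual metadata and traits as delimited
tables.  Everything is validated once on the way in; any object that survives
validation is processable by every downstream stage without further checks.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ECOTYPES = ("lean", "humper", "siscowet", "redfin")
STRATA = ("<50 m", "50-100 m", ">100 m")
#: The six net-depth categories used when three strata are too few points
#: for a Mantel test (metres; the last is open-ended).
DEPTH_CATEGORIES = ("40", "50", "80", "90", "100", ">120")

REQUIRED_METADATA_COLUMNS = (
    "individual_id",
    "ecotype",
    "zone",
    "capture_depth_m",
    "site_id",
    "lon",
    "lat",
)


class GenePopParseError(ValueError):
    """Malformed GenePop input; the message names the offending line."""


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes: individuals x loci pairs of allele codes.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` with positive integer
    allele codes and 0 meaning missing; a call is either fully typed or fully
    missing (both alleles 0).  ``populations`` carries the provisional grouping
    implied by GenePop POP blocks, when the table came from such a file.
    """

    individual_ids: list[str]
    locus_names: list[str]
    calls: np.ndarray
    populations: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n, L = len(self.individual_ids), len(self.locus_names)
        if L < 1:
            raise ValueError("at least one locus is required")
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {L} loci"
            )
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        if (self.calls < 0).any():
            raise ValueError("allele codes must be non-negative")
        half_missing = (self.calls == 0).sum(axis=2) == 1
        if half_missing.any():
            i, j = np.argwhere(half_missing)[0]
            raise ValueError(
                f"half-missing call for individual {self.individual_ids[i]!r} "
                f"at locus {self.locus_names[j]!r}: both alleles must be "
                "present or both missing"
            )
        if self.populations is not None and len(self.populations) != n:
            raise ValueError("populations must align with individuals")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (individuals x loci); True where the call is missing."""
        return self.calls[:, :, 0] == 0

    def subset_loci(self, keep: list[str]) -> "GenotypeTable":
        idx = [self.locus_names.index(name) for name in keep]
        return GenotypeTable(
            list(self.individual_ids),
            [self.locus_names[i] for i in idx],
            self.calls[:, idx, :],
            None if self.populations is None else list(self.populations),
        )

    def subset_individuals(self, keep_mask: np.ndarray) -> "GenotypeTable":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        ids = [i for i, k in zip(self.individual_ids, keep_mask) if k]
        pops = (
            None
            if self.populations is None
            else [p for p, k in zip(self.populations, keep_mask) if k]
        )
        return GenotypeTable(ids, list(self.locus_names), self.calls[keep_mask], pops)


def allele_count_matrices(
    gt: GenotypeTable,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-locus (counts, alleles) pairs for the numeric stages.

    ``counts`` is ``(n, k)`` with entries in {0,1,2}: the number of copies of
    each observed allele carried by each individual (all-zero rows are missing
    calls).  ``alleles`` lists the sorted allele codes backing the columns.
    """
    out = []
    for j in range(gt.n_loci):
        col = gt.calls[:, j, :]
        alleles = np.unique(col[col > 0])
        counts = np.zeros((gt.n_individuals, max(len(alleles), 1)), dtype=np.int8)
        for a_idx, a in enumerate(alleles):
            counts[:, a_idx] = (col == a).sum(axis=1)
        out.append((counts, alleles))
    return out


def stratum_of(depth_m: float) -> str:
    """Map a capture depth to its depth stratum.

    Bin edges are half-open: [0, 50) is shallow, [50, 100] intermediate,
    (100, inf) deep — 50 m and 100 m both land in the middle stratum.
    """
    if depth_m < 0 or not math.isfinite(depth_m):
        raise ValueError(f"invalid capture depth {depth_m!r}")
    if depth_m < 50:
        return STRATA[0]
    if depth_m <= 100:
        return STRATA[1]
    return STRATA[2]


def depth_category_of(depth_m: float) -> str:
    """Map a capture depth to the nearest of the six net-depth categories."""
    if depth_m < 0 or not math.isfinite(depth_m):
        raise ValueError(f"invalid capture depth {depth_m!r}")
    if depth_m > 110:
        return ">120"
    centres = np.array([40.0, 50.0, 80.0, 90.0, 100.0])
    return DEPTH_CATEGORIES[int(np.argmin(np.abs(centres - depth_m)))]


def depth_category_value(category: str) -> float:
    """Numeric depth (m) for a category label; '>120' is taken as 120."""
    return 120.0 if category == ">120" else float(category)


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def read_genepop(path: str | Path) -> GenotypeTable:
    """Parse a 2- or 3-digit diploid GenePop file.

    The first line is a title, the following lines name the loci (one per
    line, or a single comma-separated line), and ``POP`` markers introduce
    population blocks, which become the table's provisional ``populations``
    grouping (Pop1, Pop2, ...).  ``00``/``000`` allele fields are missing.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise GenePopParseError(f"{path}: too short to be a GenePop file")

    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise GenePopParseError(f"{path}: no POP marker found")
    if not locus_names:
        raise GenePopParseError(f"{path}: no locus names before first POP")

    ids: list[str] = []
    pops: list[str] = []
    rows: list[np.ndarray] = []
    pop_idx = 0
    digits: int | None = None
    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise GenePopParseError(
                f"{path}:{lineno + 1}: expected 'id , genotypes' line"
            )
        ind_id, geno_part = line.split(",", 1)
        ind_id = ind_id.strip()
        fields = geno_part.split()
        if len(fields) != len(locus_names):
            raise GenePopParseError(
                f"{path}:{lineno + 1}: {len(fields)} genotype fields for "
                f"{len(locus_names)} loci"
            )
        row = np.zeros((len(locus_names), 2), dtype=np.int32)
        for j, tok in enumerate(fields):
            if not re.fullmatch(r"\d+", tok) or len(tok) % 2 != 0:
                raise GenePopParseError(
                    f"{path}:{lineno + 1}: malformed allele string {tok!r} "
                    f"at locus {locus_names[j]!r} (odd length or non-digit)"
                )
            w = len(tok) // 2
            if w not in (2, 3):
                raise GenePopParseError(
                    f"{path}:{lineno + 1}: allele string {tok!r} is neither "
                    "2- nor 3-digit diploid"
                )
            if digits is None:
                digits = w
            elif w != digits:
                raise GenePopParseError(
                    f"{path}:{lineno + 1}: mixed {digits}- and {w}-digit "
                    "allele codes"
                )
            a, b = int(tok[:w]), int(tok[w:])
            if (a == 0) != (b == 0):
                raise GenePopParseError(
                    f"{path}:{lineno + 1}: half-missing genotype {tok!r}"
                )
            row[j] = (a, b)
        if ind_id in ids:
            raise GenePopParseError(
                f"{path}:{lineno + 1}: duplicated individual id {ind_id!r}"
            )
        ids.append(ind_id)
        pops.append(f"Pop{pop_idx}")
        rows.append(row)
    if not rows:
        raise GenePopParseError(f"{path}: no genotype rows")
    return GenotypeTable(ids, locus_names, np.stack(rows), pops)


def write_genepop(
    gt: GenotypeTable,
    path: str | Path,
    title: str = "depthcline export",
    grouping: list[str] | None = None,
) -> None:
    """Write a 3-digit GenePop file; ``grouping`` defines the POP blocks."""
    if (gt.calls > 999).any():
        raise ValueError("allele codes exceed the 3-digit GenePop range")
    grouping = grouping or gt.populations or ["Pop1"] * gt.n_individuals
    order = np.argsort(np.array(grouping, dtype=object), kind="stable")
    out = [title]
    out.extend(gt.locus_names)
    current = None
    for i in order:
        if grouping[i] != current:
            out.append("POP")
            current = grouping[i]
        genos = " ".join(
            f"{a:03d}{b:03d}" for a, b in gt.calls[i]
        )
        out.append(f"{gt.individual_ids[i]} , {genos}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Metadata and trait tables
# ---------------------------------------------------------------------------

LINEAR_TRAITS = ("CPD", "CPL", "HLL", "MXL", "OOL", "PCL", "PVL", "POL")
LIFE_HISTORY_TRAITS = ("t0_yr", "L0_mm", "K_per_yr", "Lmax_mm", "omega_mm_per_yr")


def validate_sample_frame(
    frame: pd.DataFrame,
    ecotypes: tuple[str, ...] = ECOTYPES,
    genotypes: GenotypeTable | None = None,
) -> pd.DataFrame:
    """Validate per-individual metadata and derive stratum/depth-category.

    Raises on missing columns, duplicated ids, unknown ecotype labels, or
    individuals present in ``genotypes`` but absent from the frame.  Returns
    a copy with ``stratum`` and ``depth_category`` columns (derived from
    ``capture_depth_m`` when absent, checked for consistency when present).
    """
    missing_cols = [c for c in REQUIRED_METADATA_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"metadata is missing columns: {missing_cols}")
    frame = frame.copy()
    frame["individual_id"] = frame["individual_id"].astype(str)
    if frame["individual_id"].duplicated().any():
        dups = frame.loc[frame["individual_id"].duplicated(), "individual_id"]
        raise ValueError(f"duplicated individual ids: {sorted(set(dups))}")
    bad = sorted(set(frame["ecotype"]) - set(ecotypes))
    if bad:
        raise ValueError(f"unknown ecotype labels: {bad} (expected {ecotypes})")
    derived = frame["capture_depth_m"].map(stratum_of)
    if "stratum" in frame.columns:
        clash = frame["stratum"].astype(str) != derived
        if clash.any():
            ids = frame.loc[clash, "individual_id"].tolist()
            raise ValueError(
                f"stratum inconsistent with capture_depth_m for: {ids}"
            )
    frame["stratum"] = derived
    if "depth_category" not in frame.columns:
        frame["depth_category"] = frame["capture_depth_m"].map(depth_category_of)
    if genotypes is not None:
        absent = sorted(set(genotypes.individual_ids) - set(frame["individual_id"]))
        if absent:
            raise ValueError(
                f"individuals present in genotypes but absent from metadata: "
                f"{absent}"
            )
    return frame


def validate_trait_table(traits: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-individual trait table.

    Requires unique ids and strictly positive standard length; where both
    Lmax and K are present, checks the early-growth identity
    omega = Lmax x K (filling the column in when absent).
    """
    if "individual_id" not in traits.columns:
        raise ValueError("trait table needs an individual_id column")
    traits = traits.copy()
    traits["individual_id"] = traits["individual_id"].astype(str)
    if traits["individual_id"].duplicated().any():
        raise ValueError("duplicated individual ids in trait table")
    if "SL_mm" in traits.columns and (traits["SL_mm"] <= 0).any():
        bad = traits.loc[traits["SL_mm"] <= 0, "individual_id"].tolist()
        raise ValueError(f"non-positive standard length for: {bad}")
    if {"Lmax_mm", "K_per_yr"} <= set(traits.columns):
        omega = traits["Lmax_mm"] * traits["K_per_yr"]
        if "omega_mm_per_yr" in traits.columns:
            if not np.allclose(
                traits["omega_mm_per_yr"], omega, rtol=1e-9, equal_nan=True
            ):
                raise ValueError("omega_mm_per_yr != Lmax_mm * K_per_yr")
        else:
            traits["omega_mm_per_yr"] = omega
    return traits


def read_tables(
    metadata_path: str | Path,
    traits_path: str | Path | None = None,
    genotypes: GenotypeTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read and validate the metadata (and optionally trait) tables."""
    frame = validate_sample_frame(pd.read_csv(metadata_path), genotypes=genotypes)
    traits = None
    if traits_path is not None:
        traits = validate_trait_table(pd.read_csv(traits_path))
        unmatched = sorted(
            set(traits["individual_id"]) - set(frame["individual_id"])
        )
        if unmatched:
            raise ValueError(
                f"trait rows without metadata: {unmatched}"
            )
    return frame, traits


def great_circle_km(
    lon1: float, lat1: float, lon2: float, lat2: float
) -> float:
    """Shortest (great-circle, haversine) distance between two points, km."""
    r = 6371.0088
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


def site_distance_matrix(sites: pd.DataFrame) -> pd.DataFrame:
    """Great-circle distance matrix (km) among sites.

    ``sites`` needs ``site_id``, ``lon``, ``lat`` columns (one row per site).
    """
    ids = sites["site_id"].tolist()
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = great_circle_km(
                sites["lon"].iloc[i],
                sites["lat"].iloc[i],
                sites["lon"].iloc[j],
                sites["lat"].iloc[j],
            )
    return pd.DataFrame(D, index=ids, columns=ids)


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
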