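"""Interval algebra and CNV callset processing.

This module turns per-algorithm CNV calls into analysis-ready units:

* multi-algorithm **consensus calls** (an event is retained only when a
  minimum number of distinct calling algorithms report it, with the calls
  agreeing by reciprocal overlap),
* cross-sample **CNV regions** (CNVRs) built by single-linkage clustering
  at a reciprocal-overlap threshold, annotated with a cohort-wide carrier
  frequency,
* rare/size filtering of CNVRs, and
* classification of large events as candidate NAHR (non-allelic homologous
  recombination) rearrangements, i.e. events whose breakpoints fall inside
  the two members of a homologous segmental-duplication pair.

Coordinates are 0-based half-open internally.  BED-style input is native;
1-based inclusive tables are accepted through a dialect flag on the readers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "GenomeManifest",
    "GenomicInterval",
    "CNVCall",
    "ConsensusCall",
    "CNVRegion",
    "SampleSheet",
    "SegDupPair",
    "DEFAULT_MANIFEST",
    "reciprocal_overlap",
    "consensus_merge",
    "cluster_cnvrs",
    "filter_rare",
    "classify_nahr",
    "compartment_of",
    "read_cnv_calls",
    "read_sample_sheet",
    "read_segdup_pairs",
]

GAIN = "gain"
LOSS = "loss"

#: Sex-chromosome labels recognised by :func:`compartment_of` (with or
#: without a "chr" prefix).
_X_LABELS = {"X", "chrX"}
_Y_LABELS = {"Y", "chrY"}


class GenomeManifest(dict):
    """Mapping chromosome label -> length in bp.

    Declares the coordinate universe: intervals on chromosomes absent from
    the manifest are rejected by the constructors that take a manifest.
    """

    @classmethod
    def from_tsv(cls, path) -> "GenomeManifest":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                         comment="#", dtype={"chrom": str})
        return cls(zip(df["chrom"], df["length"].astype(int)))

    def to_tsv(self, path) -> None:
        pd.DataFrame(sorted(self.items())).to_csv(path, sep="\t", header=False, index=False)

    @property
    def autosomes(self) -> "GenomeManifest":
        return GenomeManifest(
            (c, l) for c, l in self.items()
            if c not in _X_LABELS and c not in _Y_LABELS
        )


#: Toy genome used throughout the test suite and the simulators: 22
#: autosomes of 10 Mb plus X (8 Mb) and Y (3 Mb).  Small enough that
#: simulations run in seconds while still exercising all three chromosome
#: compartments.
DEFAULT_MANIFEST = GenomeManifest(
    {f"chr{i}": 10_000_000 for i in range(1, 23)} | {"chrX": 8_000_000, "chrY": 3_000_000}
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open 0-based genomic interval ``[start, end)``."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"malformed interval {self.chromosome}:{self.start}-{self.end} (end <= start)"
            )
        if self.start < 0:
            raise ValueError("negative start coordinate")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chromosome != other.chromosome:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class CNVCall:
    """A single algorithm's gain/loss call in one sample."""

    sample_id: str
    interval: GenomicInterval
    cnv_class: str
    algorithm: str
    platform: str = ""

    def __post_init__(self):
        if self.cnv_class not in (GAIN, LOSS):
            raise ValueError(f"cnv_class must be '{GAIN}' or '{LOSS}', got {self.cnv_class!r}")
        if not self.algorithm:
            raise ValueError("algorithm label must be nonempty")


@dataclass(frozen=True)
class ConsensusCall:
    """A CNV event supported by >= min_algorithms distinct callers.

    ``interval`` is the conservative consensus span (intersection of the
    supporting calls); ``union_interval`` retains the full extent.
    """

    sample_id: str
    interval: GenomicInterval
    cnv_class: str
    supporting_algorithms: frozenset
    union_interval: GenomicInterval | None = None
    platform: str = ""


@dataclass
class CNVRegion:
    """Cluster of reciprocally-overlapping consensus calls across samples."""

    region_id: str
    interval: GenomicInterval  # envelope
    cnv_class: str
    member_calls: list = field(default_factory=list)
    carrier_samples: set = field(default_factory=set)
    frequency: float = 0.0


@dataclass(frozen=True)
class SegDupPair:
    """Pair of homologous segmental duplications on one chromosome."""

    interval_a: GenomicInterval
    interval_b: GenomicInterval
    homology: float

    def __post_init__(self):
        if self.interval_a.chromosome != self.interval_b.chromosome:
            raise ValueError("segmental duplication pair must be intrachromosomal")
        if not 0.0 <= self.homology <= 1.0:
            raise ValueError("homology must lie in [0, 1]")


class SampleSheet:
    """Case/control sample sheet with cohort, platform and covariates.

    Backed by a DataFrame with columns ``sample_id``, ``status``
    (``case``/``control``), ``cohort``, ``platform`` and zero or more
    numeric covariate columns (``cov1``..``covK``, eigenvector loadings).
    """

    def __init__(self, df: pd.DataFrame):
        required = {"sample_id", "status", "cohort", "platform"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        bad = set(df["status"]) - {"case", "control"}
        if bad:
            raise ValueError(f"status must be case/control, got {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def sample_ids(self) -> list:
        return self.df["sample_id"].tolist()

    @property
    def covariate_columns(self) -> list:
        return [c for c in self.df.columns if c.startswith("cov")]

    @property
    def n_samples(self) -> int:
        return len(self.df)

    @property
    def n_cases(self) -> int:
        return int((self.df["status"] == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.df["status"] == "control").sum())

    def status_of(self, sample_id: str) -> str:
        row = self.df.loc[self.df["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in sample sheet")
        return row["status"].iloc[0]

    def subset(self, mask) -> "SampleSheet":
        return SampleSheet(self.df.loc[mask].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Reciprocal overlap of two intervals.

    ``min(ovl/len(a), ovl/len(b))`` where ``ovl`` is the intersection
    length; 0 for intervals on different chromosomes.  Symmetric, in [0,1];
    equals 1 only for identical intervals.
    """
    ovl = a.intersection_length(b)
    if ovl == 0:
        return 0.0
    return min(ovl / len(a), ovl / len(b))


def compartment_of(interval: GenomicInterval, manifest: GenomeManifest | None = None) -> str:
    """Map an interval to its chromosome compartment: autosome, X or Y."""
    chrom = interval.chromosome
    if manifest is not None and chrom not in manifest:
        raise KeyError(f"chromosome {chrom!r} not in genome manifest")
    if chrom in _X_LABELS:
        return "X"
    if chrom in _Y_LABELS:
        return "Y"
    return "autosome"


# ---------------------------------------------------------------------------
# Multi-algorithm consensus
# ---------------------------------------------------------------------------

def _pairwise_compatible(calls, ro_threshold: float) -> bool:
    return all(
        reciprocal_overlap(x.interval, y.interval) >= ro_threshold
        for x, y in itertools.combinations(calls, 2)
    )


def _call_sort_key(c: CNVCall):
    return (c.interval.chromosome, c.interval.start, c.interval.end, c.algorithm)


def consensus_merge(
    calls: list,
    min_algorithms: int = 2,
    ro_threshold: float = 0.5,
    max_clique_search: int = 16,
) -> list:
    """Merge one sample's per-algorithm calls into consensus calls.

    Groups same-class calls whose intervals all pairwise satisfy the
    reciprocal-overlap threshold; a group is retained only when it is
    supported by at least ``min_algorithms`` distinct algorithms.  Each
    input call joins at most one group.

    Grouping is deterministic: calls are sorted by position, the first
    unassigned call seeds a group, and the largest pairwise-compatible set
    containing the seed is taken (ties broken by position order).  Seed
    neighbourhoods larger than ``max_clique_search`` fall back to greedy
    absorption in sorted order; CNV callsets never approach this in
    practice.

    Raises ``ValueError`` on duplicate (sample, algorithm, interval) rows
    or calls from multiple samples.
    """
    if not calls:
        return []
    samples = {c.sample_id for c in calls}
    if len(samples) > 1:
        raise ValueError(f"consensus_merge expects calls from one sample, got {sorted(samples)}")
    seen = set()
    for c in calls:
        key = (c.sample_id, c.algorithm, c.interval, c.cnv_class)
        if key in seen:
            raise ValueError(f"duplicate call row: {key}")
        seen.add(key)

    out = []
    for cls in (LOSS, GAIN):
        pool = sorted((c for c in calls if c.cnv_class == cls), key=_call_sort_key)
        assigned = [False] * len(pool)
        for i, seed in enumerate(pool):
            if assigned[i]:
                continue
            neighbors = [
                j for j in range(len(pool))
                if j != i and not assigned[j]
                and reciprocal_overlap(seed.interval, pool[j].interval) >= ro_threshold
            ]
            if len(neighbors) <= max_clique_search:
                best = []
                for r in range(len(neighbors), -1, -1):
                    for combo in itertools.combinations(neighbors, r):
                        group = [seed] + [pool[j] for j in combo]
                        if _pairwise_compatible(group, ro_threshold):
                            best = list(combo)
                            break
                    if best or r == 0:
                        break
                group_idx = [i] + best
            else:  # pragma: no cover - pathological input size
                group_idx = [i]
                for j in neighbors:
                    if all(
                        reciprocal_overlap(pool[j].interval, pool[k].interval) >= ro_threshold
                        for k in group_idx
                    ):
                        group_idx.append(j)
            for j in group_idx:
                assigned[j] = True
            group = [pool[j] for j in group_idx]
            algos = frozenset(c.algorithm for c in group)
            if len(algos) < min_algorithms:
                continue
            chrom = seed.interval.chromosome
            inter = GenomicInterval(
                chrom,
                max(c.interval.start for c in group),
                min(c.interval.end for c in group),
            )
            union = GenomicInterval(
                chrom,
                min(c.interval.start for c in group),
                max(c.interval.end for c in group),
            )
            out.append(
                ConsensusCall(
                    sample_id=seed.sample_id,
                    interval=inter,
                    cnv_class=cls,
                    supporting_algorithms=algos,
                    union_interval=union,
                    platform=seed.platform,
                )
            )
    out.sort(key=lambda c: (c.interval.chromosome, c.interval.start, c.interval.end, c.cnv_class))
    return out


# ---------------------------------------------------------------------------
# CNV-region clustering and frequency annotation
# ---------------------------------------------------------------------------

def cluster_cnvrs(
    calls: list,
    samples: SampleSheet,
    ro_threshold: float = 0.5,
    envelope: bool = True,
) -> list:
    """Cluster consensus calls (across samples) into CNV regions.

    Single-linkage seeded clustering: calls are sorted by position, the
    first unassigned call seeds a region, and any same-class call with
    reciprocal overlap >= ``ro_threshold`` against the current region
    envelope (or against the seed call when ``envelope=False``) is
    absorbed; absorption repeats until the region stops growing.  Gains and
    losses never merge.  Every call lands in exactly one region.

    Region frequency is the proportion of all samples in ``samples`` (cases
    and controls combined) carrying the region.
    """
    if not 0.0 < ro_threshold <= 1.0:
        raise ValueError("ro_threshold must be in (0, 1]")
    n_total = samples.n_samples
    if n_total == 0:
        raise ValueError("empty sample sheet")

    regions = []
    by_key: dict = {}
    for c in calls:
        by_key.setdefault((c.cnv_class, c.interval.chromosome), []).append(c)
    for (cls, _chrom), pool in sorted(by_key.items()):
        pool.sort(key=lambda c: (c.interval.start, c.interval.end, c.sample_id))
        assigned = [False] * len(pool)
        for i, seed in enumerate(pool):
            if assigned[i]:
                continue
            members = [i]
            assigned[i] = True
            env = seed.interval
            ref = seed.interval
            grew = True
            while grew:
                grew = False
                target = env if envelope else ref
                # pool is sorted by start; calls starting at/after env.end
                # cannot overlap the envelope, so the scan stops there.
                for j in range(i + 1, len(pool)):
                    if pool[j].interval.start >= env.end:
                        break
                    if assigned[j]:
                        continue
                    if reciprocal_overlap(target, pool[j].interval) >= ro_threshold:
                        members.append(j)
                        assigned[j] = True
                        env = GenomicInterval(
                            env.chromosome,
                            min(env.start, pool[j].interval.start),
                            max(env.end, pool[j].interval.end),
                        )
                        grew = True
            member_calls = [pool[j] for j in members]
            carriers = {c.sample_id for c in member_calls}
            regions.append(
                CNVRegion(
                    region_id="",
                    interval=env,
                    cnv_class=cls,
                    member_calls=member_calls,
                    carrier_samples=carriers,
                    frequency=len(carriers) / n_total,
                )
            )
    regions.sort(key=lambda r: (r.interval.chromosome, r.interval.start, r.interval.end, r.cnv_class))
    for k, r in enumerate(regions):
        r.region_id = f"cnvr_{k:05d}"
    return regions


def filter_rare(
    regions: list,
    max_freq: float = 0.05,
    min_size: int = 0,
    cnv_class: str | None = None,
) -> list:
    """Keep rare regions: frequency strictly below ``max_freq`` (the
    "less than 5%" rule), envelope length >= ``min_size``, and matching
    class when one is given.  Idempotent; returns a subset of the input."""
    out = []
    for r in regions:
        if r.frequency >= max_freq:
            continue
        if len(r.interval) < min_size:
            continue
        if cnv_class is not None and r.cnv_class != cnv_class:
            continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# NAHR hotspot classification
# ---------------------------------------------------------------------------

def classify_nahr(
    call: ConsensusCall,
    segdups: list,
    min_size: int = 100_000,
    slack: int = 20_000,
) -> bool:
    """Is this call a candidate recurrent NAHR rearrangement?

    True iff the call is at least ``min_size`` long and its two breakpoints
    each fall within ``slack`` bp of (one of) the two members of a single
    homologous segmental-duplication pair, in either orientation.  The
    default slack of 20 kb reflects breakpoint uncertainty from array probe
    spacing.
    """
    iv = call.interval
    if len(iv) < min_size:
        return False

    def near(pos: int, dup: GenomicInterval) -> bool:
        return dup.start - slack <= pos <= dup.end + slack

    for pair in segdups:
        if pair.interval_a.chromosome != iv.chromosome:
            continue
        a, b = pair.interval_a, pair.interval_b
        if (near(iv.start, a) and near(iv.end, b)) or (near(iv.start, b) and near(iv.end, a)):
            return True
    return False


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_cnv_calls(path, dialect: str = "bed") -> list:
    """Read a CNV call table.

    TSV with header ``sample_id, chrom, start, end, class, algorithm,
    platform``.  ``dialect='bed'`` (default) treats coordinates as 0-based
    half-open; ``dialect='one_based'`` as 1-based inclusive (converted on
    input).
    """
    if dialect not in ("bed", "one_based"):
        raise ValueError(f"unknown coordinate dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    if "class" in df.columns:
        df = df.rename(columns={"class": "cnv_class"})
    calls = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if dialect == "one_based":
            start -= 1
        calls.append(
            CNVCall(
                sample_id=row.sample_id,
                interval=GenomicInterval(row.chrom, start, end),
                cnv_class=row.cnv_class,
                algorithm=row.algorithm,
                platform=str(getattr(row, "platform", "") or ""),
            )
        )
    return calls


def write_cnv_calls(calls: list, path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "chrom": c.interval.chromosome,
            "start": c.interval.start,
            "end": c.interval.end,
            "cnv_class": c.cnv_class,
            "algorithm": c.algorithm,
            "platform": c.platform,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "cnv_class",
                                "algorithm", "platform"]).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet.from_tsv(path)


def read_segdup_pairs(path) -> list:
    """Read a paired-BED segdup table: chromA startA endA chromB startB endB homology."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chromA", "startA", "endA", "chromB", "startB", "endB", "homology"],
        dtype={"chromA": str, "chromB": str},
    )
    return [
        SegDupPair(
            GenomicInterval(r.chromA, int(r.startA), int(r.endA)),
            GenomicInterval(r.chromB, int(r.startB), int(r.endB)),
            float(r.homology),
        )
        for r in df.itertuples(index=False)
    ]
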