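"""Homozygosity-by-descent (HBD) segment post-processing and inbreeding.

Segment calls from a haplotype-model HBD caller are taken as input; this
module (i) removes segments that are artifacts of large hemizygous
deletions (a deletion makes the remaining single haplotype look
homozygous), (ii) estimates the per-sample inbreeding coefficient F as the
fraction of the autosomal genome covered by HBD segments, (iii) classifies
samples against the conventional F threshold ladder (0.5%, 1.6%, 6.25%),
(iv) flags whole-chromosome uniparental isodisomy (UPD), and (v) tests for
association between inbreeding and case status.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cnv_core import GenomeManifest, GenomicInterval, SampleSheet, reciprocal_overlap
from .burden_stats import BurdenFit, logistic_burden

__all__ = [
    "HBDSegment",
    "InbreedingProfile",
    "UPDFlag",
    "filter_deletion_artifacts",
    "inbreeding_coefficient",
    "classify_f",
    "detect_upd",
    "inbreeding_association",
    "read_hbd_segments",
    "F_THRESHOLDS",
]

#: Conventional inbreeding-classification ladder: offspring of second
#: cousins (~0.5%), between second and first cousins (1.6%), closer than
#: first cousins (6.25% = 1/16, the first-cousin expectation).
F_THRESHOLDS = (0.005, 0.016, 0.0625)


@dataclass(frozen=True)
class HBDSegment:
    sample_id: str
    interval: GenomicInterval


@dataclass
class InbreedingProfile:
    sample_id: str
    f_hat: float
    n_segments: int
    hbd_bp: int
    genome_bp: int


@dataclass(frozen=True)
class UPDFlag:
    sample_id: str
    chromosome: str
    covered_fraction: float


def read_hbd_segments(path, dialect: str = "bed") -> list:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    off = 1 if dialect == "one_based" else 0
    return [
        HBDSegment(r.sample_id, GenomicInterval(r.chrom, int(r.start) - off, int(r.end)))
        for r in df.itertuples(index=False)
    ]


def write_hbd_segments(segments: list, path) -> None:
    pd.DataFrame(
        [
            {"sample_id": s.sample_id, "chrom": s.interval.chromosome,
             "start": s.interval.start, "end": s.interval.end}
            for s in segments
        ],
        columns=["sample_id", "chrom", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


def _union_length(intervals: list) -> int:
    """Total covered bp of possibly-overlapping intervals on one chromosome."""
    if not intervals:
        return 0
    ivs = sorted((iv.start, iv.end) for iv in intervals)
    total = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def filter_deletion_artifacts(
    segments: list,
    deletions: list,
    ro_threshold: float = 0.5,
) -> tuple:
    """Split HBD segments into (kept, removed) by deletion overlap.

    A segment is removed when it has reciprocal overlap >= ``ro_threshold``
    with a deletion call *in the same sample* — such segments are
    hemizygosity artifacts, not true autozygosity.  ``kept + removed``
    partitions the input exactly.
    """
    dels_by_sample: dict = {}
    for d in deletions:
        if d.cnv_class == "loss":
            dels_by_sample.setdefault(d.sample_id, []).append(d.interval)
    kept, removed = [], []
    for seg in segments:
        hits = dels_by_sample.get(seg.sample_id, ())
        if any(reciprocal_overlap(seg.interval, dv) >= ro_threshold for dv in hits):
            removed.append(seg)
        else:
            kept.append(seg)
    return kept, removed


def inbreeding_coefficient(
    segments: list,
    genome_manifest: GenomeManifest,
    min_segment: int = 0,
    sample_ids: list | None = None,
) -> list:
    """Per-sample inbreeding coefficient F from HBD segments.

    F = (union of autosomal HBD segment lengths >= ``min_segment``) /
    (total autosomal length in the manifest).  Sex chromosomes are
    excluded: the male X is hemizygous and carries no autozygosity signal.
    ``sample_ids`` forces zero-F profiles for samples without segments.
    """
    autosomes = genome_manifest.autosomes
    genome_bp = sum(autosomes.values())
    if genome_bp == 0:
        raise ValueError("manifest has no autosomes")

    by_sample: dict = {}
    for seg in segments:
        if seg.interval.chromosome not in autosomes:
            continue
        if len(seg.interval) < min_segment:
            continue
        by_sample.setdefault(seg.sample_id, []).append(seg.interval)

    ids = sample_ids if sample_ids is not None else sorted(by_sample)
    profiles = []
    for sid in ids:
        ivs = by_sample.get(sid, [])
        by_chrom: dict = {}
        for iv in ivs:
            by_chrom.setdefault(iv.chromosome, []).append(iv)
        hbd_bp = sum(_union_length(v) for v in by_chrom.values())
        profiles.append(
            InbreedingProfile(
                sample_id=sid,
                f_hat=hbd_bp / genome_bp,
                n_segments=len(ivs),
                hbd_bp=hbd_bp,
                genome_bp=genome_bp,
            )
        )
    return profiles


def classify_f(profile: InbreedingProfile, thresholds=F_THRESHOLDS) -> dict:
    """Strict-inequality membership of F against the threshold ladder."""
    return {t: profile.f_hat > t for t in thresholds}


def detect_upd(
    segments: list,
    genome_manifest: GenomeManifest,
    coverage_threshold: float = 0.9,
) -> list:
    """Flag (sample, chromosome) pairs with near-complete HBD coverage.

    A chromosome almost fully homozygous-by-descent in one sample is the
    signature of uniparental isodisomy.  Coverage is the union of the
    sample's segments on that chromosome over the manifest length.
    """
    by_key: dict = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.interval.chromosome), []).append(seg.interval)
    flags = []
    for (sid, chrom), ivs in sorted(by_key.items()):
        length = genome_manifest.get(chrom)
        if not length:
            continue
        frac = _union_length(ivs) / length
        if frac >= coverage_threshold:
            flags.append(UPDFlag(sid, chrom, frac))
    return flags


def inbreeding_association(
    profiles: list,
    samples: SampleSheet,
    mode: str = "continuous",
    threshold: float = 0.0625,
    covariates: bool = True,
) -> BurdenFit:
    """Logistic association between inbreeding and case status.

    ``mode='continuous'`` regresses case status on F itself (the reported
    beta is log-odds per unit F); ``mode='categorical'`` regresses on the
    indicator F > ``threshold``.  Ancestry covariates from the sheet are
    included by default; separation is flagged as in the burden fit.
    """
    f = {p.sample_id: p.f_hat for p in profiles}
    if mode == "continuous":
        x = [f.get(s, 0.0) for s in samples.sample_ids]
    elif mode == "categorical":
        x = [1.0 if f.get(s, 0.0) > threshold else 0.0 for s in samples.sample_ids]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return logistic_burden(pd.Series(x, index=samples.sample_ids), samples, covariates=covariates)
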