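"""Synthetic cohort generators with known ground truth.

Every input the analysis pipeline consumes can be produced here with its
generative parameters recorded, so each downstream stage is testable
end-to-end without external data:

* ``simulate_cnv_cohort`` — multi-cohort, multi-platform CNV callsets.
  Each sample carries common CNVs at fixed polymorphic loci plus rare
  events (Poisson per compartment and class, log-normal sizes); case
  status is drawn from a logistic model of the rare event counts with
  injectable per-event log-odds, and each true event is emitted per
  calling algorithm with configurable sensitivity and breakpoint jitter,
  so 2-of-3 consensus recovery is a measurable channel property.
* ``simulate_hbd`` — homozygosity-by-descent tracts: autozygous segments
  with exponential lengths (mean 100/(2g) cM for a common ancestor g
  meioses away on each side, at a uniform 1 cM/Mb map), short background
  homozygosity, and optional whole-chromosome UPD injection.
* ``simulate_exome`` — a reference panel plus one subject exome with
  benign-skewed beta-distributed annotation scores and a single planted
  homozygous, maximal-impact variant in a panel-novel gene.

Default cohort sizes (83/62, 179/974, 61/100 cases/controls on three
platforms) mirror a realistic multi-center rare-variant study; all
randomness flows from a single integer seed and fixed seeds reproduce
byte-identical output tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .cnv_core import (
    DEFAULT_MANIFEST,
    CNVCall,
    GenomeManifest,
    GenomicInterval,
    SampleSheet,
)
from .hbd import HBDSegment

__all__ = [
    "CohortSpec",
    "CNVModel",
    "AlgorithmModel",
    "HBDModel",
    "VariantModel",
    "SimulationConfig",
    "GroundTruth",
    "STUDY_COHORTS",
    "HBD_AUTOSOMES",
    "simulate_cnv_cohort",
    "simulate_hbd",
    "simulate_exome",
]

import pandas as pd


@dataclass
class CohortSpec:
    name: str
    n_case: int
    n_control: int
    platform: str


#: Three case-control cohorts on three array platforms: 323 cases and
#: 1136 controls in total.
STUDY_COHORTS = [
    CohortSpec("cohort1", 83, 62, "illumina370k"),
    CohortSpec("cohort2", 179, 974, "affy6"),
    CohortSpec("cohort3", 61, 100, "omniexpress"),
]


@dataclass
class CNVModel:
    common_region_count: int = 20
    common_freq_range: tuple = (0.05, 0.4)
    #: Poisson rate of rare events per genome, keyed (compartment, class).
    rare_rate: dict = field(
        default_factory=lambda: {
            ("autosome", "loss"): 1.0,
            ("autosome", "gain"): 1.0,
            ("X", "loss"): 0.15,
            ("X", "gain"): 0.15,
            ("Y", "loss"): 0.05,
            ("Y", "gain"): 0.05,
        }
    )
    #: Log-normal rare-event size: median 30 kb, sigma(log) 1.2 —
    #: populates both the <100 kb and >100 kb strata.
    size_log_median: float = math.log(30_000)
    size_log_sd: float = 1.2


@dataclass
class AlgorithmModel:
    algorithms: tuple = ("algA", "algB", "algC")
    sensitivity: tuple = (1.0, 0.9, 0.9)
    breakpoint_jitter_sd: float = 2_000.0


@dataclass
class HBDModel:
    #: meioses to the shared ancestor on each side; 3 = first cousins.
    generations: int = 3
    #: target inbreeding coefficient; 1/16 for first-cousin offspring.
    f_target: float = 1.0 / 16.0
    #: diffuse short background homozygosity (all samples).
    background_f: float = 0.001
    background_mean_bp: float = 500_000.0
    cm_per_mb: float = 1.0
    upd_samples: dict = field(default_factory=dict)  # sample_id -> chromosome


@dataclass
class VariantModel:
    n_genes: int = 1000
    panel_gene_fraction: float = 0.9
    n_panel_variants: int = 5000
    n_subject_variants: int = 300
    #: benign-skewed Beta parameters for normalized annotation scores.
    score_beta: tuple = (0.8, 3.0)
    hom_fraction: float = 0.05
    plant_hit: bool = True


@dataclass
class SimulationConfig:
    seed: int = 0
    cohorts: list = field(default_factory=lambda: [CohortSpec(**asdict(c)) for c in STUDY_COHORTS])
    genome: GenomeManifest = field(default_factory=lambda: GenomeManifest(DEFAULT_MANIFEST))
    cnv_model: CNVModel = field(default_factory=CNVModel)
    #: per-event log-odds of case status, keyed (compartment, class).
    burden_effect: dict = field(default_factory=lambda: {("autosome", "loss"): math.log(1.10)})
    algorithm_model: AlgorithmModel = field(default_factory=AlgorithmModel)
    hbd_model: HBDModel = field(default_factory=HBDModel)
    variant_model: VariantModel = field(default_factory=VariantModel)
    n_covariates: int = 10


@dataclass
class GroundTruth:
    """Generative parameters and per-sample truth, serializable to JSON."""

    true_events: dict = field(default_factory=dict)  # sample -> list of event dicts
    burden_betas: dict = field(default_factory=dict)  # "compartment:class" -> beta
    true_f: dict = field(default_factory=dict)  # sample -> F target (hbd)
    upd: dict = field(default_factory=dict)  # sample -> chromosome
    planted_variant: str | None = None
    common_regions: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "true_events": self.true_events,
                    "burden_betas": {f"{k[0]}:{k[1]}": v for k, v in self.burden_betas.items()},
                    "true_f": self.true_f,
                    "upd": self.upd,
                    "planted_variant": self.planted_variant,
                    "common_regions": self.common_regions,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


# ---------------------------------------------------------------------------
# CNV cohorts
# ---------------------------------------------------------------------------

def _compartment_chroms(genome: GenomeManifest):
    auto, x, y = [], [], []
    for c in genome:
        if c in ("chrX", "X"):
            x.append(c)
        elif c in ("chrY", "Y"):
            y.append(c)
        else:
            auto.append(c)
    return {"autosome": auto, "X": x, "Y": y}


def _draw_rare_events(rng, genome, model: CNVModel):
    comps = _compartment_chroms(genome)
    events = []
    for (comp, cls), lam in model.rare_rate.items():
        chroms = comps[comp]
        if not chroms:
            continue
        lengths = np.array([genome[c] for c in chroms], dtype=float)
        weights = lengths / lengths.sum()
        n = rng.poisson(lam)
        for _ in range(n):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            size = int(np.clip(rng.lognormal(model.size_log_median, model.size_log_sd),
                               1_000, genome[chrom] - 1))
            start = int(rng.integers(0, genome[chrom] - size))
            events.append({"chrom": chrom, "start": start, "end": start + size,
                           "cnv_class": cls, "compartment": comp, "origin": "rare"})
    return events


def _emit_calls(rng, sample_id, platform, events, genome, alg_model: AlgorithmModel):
    calls = []
    for ev in events:
        for alg, sens in zip(alg_model.algorithms, alg_model.sensitivity):
            if rng.random() > sens:
                continue
            j1 = int(rng.normal(0, alg_model.breakpoint_jitter_sd))
            j2 = int(rng.normal(0, alg_model.breakpoint_jitter_sd))
            s = max(0, ev["start"] + j1)
            e = min(genome[ev["chrom"]], ev["end"] + j2)
            if e <= s:
                s, e = ev["start"], ev["end"]
            calls.append(
                CNVCall(
                    sample_id=sample_id,
                    interval=GenomicInterval(ev["chrom"], s, e),
                    cnv_class=ev["cnv_class"],
                    algorithm=alg,
                    platform=platform,
                )
            )
    return calls


def simulate_cnv_cohort(config: SimulationConfig, seed: int | None = None):
    """Simulate multi-cohort CNV callsets with injected burden effects.

    Returns ``(calls, sample_sheet, ground_truth)`` where ``calls`` is a
    flat list of per-algorithm :class:`CNVCall` rows across all cohorts.

    Case/control status: every candidate individual draws common-region
    carriage and rare events; the probability of being a case is
    ``expit(alpha_cohort + sum(beta[comp,class] * n_rare_events))`` with
    ``alpha_cohort`` set to the cohort's target case fraction.  Sampling
    then keeps the requested numbers of cases and controls, which leaves
    the per-event log-odds identifiable by retrospective logistic
    regression.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genome = config.genome
    model = config.cnv_model
    total_n = sum(c.n_case + c.n_control for c in config.cohorts)
    if total_n == 0:
        raise ValueError("infeasible config: no samples requested")

    # common polymorphic CNV loci, shared across cohorts
    comps = _compartment_chroms(genome)
    common = []
    for k in range(model.common_region_count):
        chrom = comps["autosome"][int(rng.integers(len(comps["autosome"])))]
        size = int(np.clip(rng.lognormal(model.size_log_median, model.size_log_sd),
                           5_000, genome[chrom] // 10))
        start = int(rng.integers(0, genome[chrom] - size))
        freq = float(rng.uniform(*model.common_freq_range))
        cls = "loss" if rng.random() < 0.5 else "gain"
        common.append({"chrom": chrom, "start": start, "end": start + size,
                       "cnv_class": cls, "frequency": freq, "id": f"common_{k:03d}"})

    truth = GroundTruth(burden_betas=dict(config.burden_effect), common_regions=common)
    all_calls = []
    sheet_rows = []
    cov_shift = {c.name: rng.normal(0, 0.5, size=config.n_covariates) for c in config.cohorts}

    for cohort in config.cohorts:
        n_case, n_control = cohort.n_case, cohort.n_control
        if n_case <= 0 or n_control <= 0:
            raise ValueError(f"infeasible cohort {cohort.name}: needs cases and controls")
        alpha = math.log(n_case / n_control)
        cases, controls = [], []
        guard = 0
        while (len(cases) < n_case or len(controls) < n_control) and guard < 50:
            guard += 1
            batch = int(2.2 * (n_case + n_control))
            for _ in range(batch):
                events = _draw_rare_events(rng, genome, model)
                eta = alpha
                for ev in events:
                    eta += config.burden_effect.get((ev["compartment"], ev["cnv_class"]), 0.0)
                is_case = rng.random() < 1.0 / (1.0 + math.exp(-eta))
                bucket = cases if is_case else controls
                if len(bucket) < (n_case if is_case else n_control):
                    bucket.append(events)
        if len(cases) < n_case or len(controls) < n_control:  # pragma: no cover
            raise ValueError(f"infeasible config: cohort {cohort.name} produced too few "
                             f"{'cases' if len(cases) < n_case else 'controls'}")

        idx = 0
        for status, bucket in (("case", cases), ("control", controls)):
            for events in bucket:
                sid = f"{cohort.name}_{status}_{idx:04d}"
                idx += 1
                # common-region carriage
                sample_events = list(events)
                for reg in common:
                    if rng.random() < reg["frequency"]:
                        sample_events.append({**reg, "compartment": "autosome", "origin": "common"})
                truth.true_events[sid] = [
                    {k: ev[k] for k in ("chrom", "start", "end", "cnv_class", "origin")}
                    for ev in sample_events
                ]
                all_calls.extend(
                    _emit_calls(rng, sid, cohort.platform, sample_events, genome,
                                config.algorithm_model)
                )
                row = {"sample_id": sid, "status": status, "cohort": cohort.name,
                       "platform": cohort.platform}
                covs = rng.normal(0, 1, size=config.n_covariates) + cov_shift[cohort.name]
                row.update({f"cov{j + 1}": covs[j] for j in range(config.n_covariates)})
                sheet_rows.append(row)

    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    return all_calls, sheet, truth


# ---------------------------------------------------------------------------
# HBD tracts
# ---------------------------------------------------------------------------

#: Real-scale autosomal manifest (approximate human autosome lengths, Mb
#: resolution, ~2.88 Gb total).  Autozygous tracts of recent inbreeding
#: average tens of Mb, so a toy 10 Mb-per-chromosome genome would truncate
#: them; HBD simulation therefore defaults to this manifest.
HBD_AUTOSOMES = GenomeManifest(
    {
        "chr1": 247_000_000, "chr2": 243_000_000, "chr3": 199_000_000,
        "chr4": 191_000_000, "chr5": 181_000_000, "chr6": 171_000_000,
        "chr7": 159_000_000, "chr8": 146_000_000, "chr9": 140_000_000,
        "chr10": 135_000_000, "chr11": 134_000_000, "chr12": 132_000_000,
        "chr13": 114_000_000, "chr14": 106_000_000, "chr15": 100_000_000,
        "chr16": 89_000_000, "chr17": 79_000_000, "chr18": 76_000_000,
        "chr19": 64_000_000, "chr20": 62_000_000, "chr21": 47_000_000,
        "chr22": 50_000_000,
    }
)


def _place_segments(rng, sample_id, genome, total_rate_bp, mean_len_bp):
    """Poisson-process placement on the concatenated genome.

    Segment starts are uniform on the concatenated autosomes and lengths
    exponential; segments spilling over a chromosome boundary are split,
    so covered length is preserved (no edge truncation except at the
    genome end).
    """
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    offsets = np.concatenate([[0.0], np.cumsum(lengths)])
    G = offsets[-1]
    n = rng.poisson(total_rate_bp / mean_len_bp)
    segments = []
    for _ in range(n):
        start = rng.uniform(0, G)
        length = rng.exponential(mean_len_bp)
        end = min(start + length, G)
        # split across chromosome boundaries
        pos = start
        while pos < end:
            ci = int(np.searchsorted(offsets, pos, side="right") - 1)
            chrom_end = offsets[ci + 1]
            s = int(pos - offsets[ci])
            e = int(min(end, chrom_end) - offsets[ci])
            if e > s:
                segments.append(HBDSegment(sample_id, GenomicInterval(chroms[ci], s, e)))
            pos = min(end, chrom_end)
            if pos == chrom_end and pos < end:
                continue
            break
    return segments


def simulate_hbd(
    config: SimulationConfig,
    sample_ids: list | None = None,
    inbred: bool = True,
    genome: GenomeManifest | None = None,
    seed: int | None = None,
):
    """Simulate HBD segment tables with known inbreeding.

    For each sample: autozygous tracts from a common ancestor ``g``
    meioses away per side (exponential lengths, mean ``100/(2g)`` cM at
    1 cM/Mb; expected genome fraction ``f_target``), plus short background
    homozygosity; optional whole-chromosome UPD injection via
    ``config.hbd_model.upd_samples``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    model = config.hbd_model
    genome = HBD_AUTOSOMES if genome is None else genome
    G = sum(genome.autosomes.values())
    if sample_ids is None:
        sample_ids = [f"s{i:04d}" for i in range(100)]

    mean_len_bp = (100.0 / (2 * model.generations)) / model.cm_per_mb * 1e6
    truth = GroundTruth(upd=dict(model.upd_samples))
    segments = []
    for sid in sample_ids:
        f = model.f_target if inbred else 0.0
        truth.true_f[sid] = f
        if f > 0:
            segments.extend(_place_segments(rng, sid, genome.autosomes, f * G, mean_len_bp))
        if model.background_f > 0:
            segments.extend(
                _place_segments(rng, sid, genome.autosomes,
                                model.background_f * G, model.background_mean_bp)
            )
        chrom = model.upd_samples.get(sid)
        if chrom:
            segments.append(HBDSegment(sid, GenomicInterval(chrom, 0, genome[chrom])))
    segments.sort(key=lambda s: (s.sample_id, s.interval.chromosome, s.interval.start))
    return segments, truth


# ---------------------------------------------------------------------------
# Exomes
# ---------------------------------------------------------------------------

def _raw_from_normalized(x: dict):
    """Map normalized [0,1] damage scores back to raw annotator scales."""
    from .varscore import DEFAULT_NORMALIZATION

    raw = {}
    for a, v in x.items():
        r = DEFAULT_NORMALIZATION.ranges[a]
        val = v if r.ascending else 1.0 - v
        raw[a] = r.lo + val * (r.hi - r.lo)
    return raw


def simulate_exome(config: SimulationConfig, seed: int | None = None):
    """Simulate a reference variant panel plus one subject exome.

    Annotation scores are drawn benign-skewed (Beta) in normalized space
    and mapped back to each annotator's raw scale.  When
    ``variant_model.plant_hit`` is set, one homozygous variant with
    near-maximal scores is planted in a gene absent from the panel, with
    reference MAFs below the 10% rarity filter — the structural analogue
    of a private homozygous knockout surfacing above the panel background.

    Returns ``(subject_variants, panel_variants, ground_truth)``.
    """
    from .varscore import ANNOTATORS, AnnotatedVariant

    rng = np.random.default_rng(config.seed if seed is None else seed)
    vm = config.variant_model
    genes = [f"gene{g:04d}" for g in range(vm.n_genes)]
    n_panel_genes = int(vm.panel_gene_fraction * vm.n_genes)
    panel_genes = genes[:n_panel_genes]
    novel_genes = genes[n_panel_genes:]
    a, b = vm.score_beta

    def draw_variant(idx, prefix, gene_pool, ploidy=None):
        gene = gene_pool[int(rng.integers(len(gene_pool)))]
        norm = {an: float(rng.beta(a, b)) for an in ANNOTATORS}
        if ploidy is None:
            ploidy = 2 if rng.random() < vm.hom_fraction else 1
        maf1 = float(rng.beta(0.5, 5.0) * 0.5)
        maf2 = float(rng.beta(0.5, 5.0) * 0.5)
        return AnnotatedVariant(
            variant_id=f"{prefix}{idx:05d}",
            gene=gene,
            ploidy=ploidy,
            raw_scores=_raw_from_normalized(norm),
            maf_panel_1=maf1,
            maf_panel_2=maf2,
        )

    panel = [draw_variant(i, "pv", panel_genes, ploidy=1) for i in range(vm.n_panel_variants)]
    subject = [draw_variant(i, "sv", genes) for i in range(vm.n_subject_variants)]

    truth = GroundTruth()
    if vm.plant_hit:
        if not novel_genes:
            raise ValueError("plant_hit requires panel_gene_fraction < 1")
        gene = novel_genes[int(rng.integers(len(novel_genes)))]
        norm = {an: float(rng.uniform(0.95, 1.0)) for an in ANNOTATORS}
        hit = AnnotatedVariant(
            variant_id="sv_planted",
            gene=gene,
            ploidy=2,
            raw_scores=_raw_from_normalized(norm),
            maf_panel_1=float(rng.uniform(0, 0.05)),
            maf_panel_2=float(rng.uniform(0, 0.05)),
        )
        subject.append(hit)
        truth.planted_variant = hit.variant_id
    return subject, panel, truth
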