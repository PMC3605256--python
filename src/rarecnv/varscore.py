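"""Two-dimensional exome variant prioritization.

Each exome variant carries five deleteriousness annotations — two
conservation scores (phyloP, GERP), two protein-impact predictors
(PolyPhen2, SIFT) and one likelihood-ratio test (LRT).  Each raw score is
affinely normalized to [0,1] with 1 = most damaging (SIFT is flipped:
low raw SIFT means damaging).  The **Individual Score**

    P_ind = ploidy x sum(5 normalized scores)        in [0, 10]

weights a variant's summed impact by the ploidy of the mutant allele (1
for heterozygous, 2 for homozygous).  The **Population Score** rescales
P_ind by the most damaging variant already segregating in the same gene
in a reference panel:

    P_pop = P_ind - P_max(gene)

where P_max is the maximum panel P_ind per gene (0 for genes absent from
the panel, so variants in panel-novel genes rank highest).  Only variants
rare in *both* reference frequency panels (MAF < 10% in each) are
considered; ranking is by descending (P_pop, P_ind) with the variant id
as the final tie-break.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger("rarecnv")

__all__ = [
    "AnnotatedVariant",
    "NormalizationSpec",
    "DEFAULT_NORMALIZATION",
    "ScoredVariant",
    "ANNOTATORS",
    "normalize_scores",
    "individual_score",
    "build_gene_max",
    "population_score",
    "maf_filter",
    "rank_variants",
    "score_variants",
    "read_variants",
]

ANNOTATORS = ("phylop", "polyphen2", "sift", "gerp", "lrt")


@dataclass(frozen=True)
class AnnotatedVariant:
    variant_id: str
    gene: str
    ploidy: int  # 1 heterozygous, 2 homozygous
    raw_scores: dict  # annotator -> raw value (may be None for missing)
    maf_panel_1: float = 0.0
    maf_panel_2: float = 0.0

    def __post_init__(self):
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 (het) or 2 (hom)")
        for m in (self.maf_panel_1, self.maf_panel_2):
            if not 0.0 <= m <= 0.5:
                raise ValueError("minor allele frequency must lie in [0, 0.5]")


@dataclass(frozen=True)
class _Range:
    lo: float
    hi: float
    ascending: bool = True  # True: high raw = damaging; False: flip


@dataclass
class NormalizationSpec:
    """Per-annotator affine normalization ranges and directions."""

    ranges: dict = field(default_factory=dict)
    missing_policy: str = "zero"  # zero (benign) | drop

    def normalize_one(self, annotator: str, raw) -> float | None:
        r = self.ranges[annotator]
        if raw is None or (isinstance(raw, float) and raw != raw):  # NaN
            if self.missing_policy == "drop":
                return None
            logger.debug("missing %s score treated as benign (0)", annotator)
            return 0.0
        x = (float(raw) - r.lo) / (r.hi - r.lo)
        if x < 0.0 or x > 1.0:
            logger.debug("clamping out-of-range %s score %s", annotator, raw)
            x = min(max(x, 0.0), 1.0)
        return x if r.ascending else 1.0 - x


#: Default normalization: published theoretical ranges per annotator, with
#: SIFT direction-flipped (raw 0 = damaging).
DEFAULT_NORMALIZATION = NormalizationSpec(
    ranges={
        "phylop": _Range(-14.0, 6.0, True),
        "gerp": _Range(-12.3, 6.17, True),
        "polyphen2": _Range(0.0, 1.0, True),
        "sift": _Range(0.0, 1.0, False),
        "lrt": _Range(0.0, 1.0, True),
    }
)


@dataclass
class ScoredVariant:
    variant: AnnotatedVariant
    normalized: dict
    p_ind: float
    p_pop: float | None = None


def normalize_scores(variant: AnnotatedVariant, spec: NormalizationSpec = DEFAULT_NORMALIZATION) -> dict | None:
    """Normalize the five raw annotations to [0,1], 1 = most damaging.

    Returns None when a score is missing and the spec's missing policy is
    ``drop``.
    """
    out = {}
    for a in ANNOTATORS:
        v = spec.normalize_one(a, variant.raw_scores.get(a))
        if v is None:
            return None
        out[a] = v
    return out


def individual_score(normalized: dict, ploidy: int) -> float:
    """P_ind = ploidy x sum of the five normalized scores, in [0, 10]."""
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    total = sum(normalized[a] for a in ANNOTATORS)
    return ploidy * total


def build_gene_max(panel: list, spec: NormalizationSpec = DEFAULT_NORMALIZATION) -> dict:
    """Per-gene maximum panel Individual Score (P_max).

    Panel genotype ploidy is used when present; genes with no panel
    variants are simply absent (lookup convention: 0).
    """
    table: dict = {}
    for v in panel:
        norm = normalize_scores(v, spec)
        if norm is None:
            continue
        p = individual_score(norm, v.ploidy)
        if p > table.get(v.gene, float("-inf")):
            table[v.gene] = p
    return table


def population_score(p_ind: float, gene: str, gene_max: dict) -> float:
    """P_pop = P_ind - P_max(gene); negative when the panel already holds
    a more damaging variant in the gene."""
    return p_ind - gene_max.get(gene, 0.0)


def maf_filter(variants: list, max_maf: float = 0.10) -> list:
    """Keep variants rare in both reference panels (strict < in each)."""
    return [v for v in variants if v.maf_panel_1 < max_maf and v.maf_panel_2 < max_maf]


def score_variants(
    variants: list,
    gene_max: dict,
    spec: NormalizationSpec = DEFAULT_NORMALIZATION,
    max_maf: float | None = 0.10,
) -> list:
    """Normalize, score and population-rescale a variant list."""
    if max_maf is not None:
        variants = maf_filter(variants, max_maf)
    out = []
    for v in variants:
        norm = normalize_scores(v, spec)
        if norm is None:
            continue
        p_ind = individual_score(norm, v.ploidy)
        out.append(ScoredVariant(v, norm, p_ind, population_score(p_ind, v.gene, gene_max)))
    return out


def rank_variants(scored: list) -> list:
    """Total order: descending P_pop, then descending P_ind, then id."""
    return sorted(scored, key=lambda s: (-s.p_pop, -s.p_ind, s.variant.variant_id))


def read_variants(path) -> list:
    """Read an annotated variant TSV.

    Columns: variant_id, gene, ploidy, phylop, polyphen2, sift, gerp, lrt,
    maf1, maf2 (chrom/pos columns, if present, are carried in the id).
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene": str})
    out = []
    for r in df.itertuples(index=False):
        raw = {a: getattr(r, a, None) for a in ANNOTATORS}
        out.append(
            AnnotatedVariant(
                variant_id=r.variant_id,
                gene=r.gene,
                ploidy=int(r.ploidy),
                raw_scores=raw,
                maf_panel_1=float(getattr(r, "maf1", 0.0)),
                maf_panel_2=float(getattr(r, "maf2", 0.0)),
            )
        )
    return out


def write_variants(variants: list, path) -> None:
    rows = []
    for v in variants:
        row = {"variant_id": v.variant_id, "gene": v.gene, "ploidy": v.ploidy}
        row.update({a: v.raw_scores.get(a) for a in ANNOTATORS})
        row["maf1"] = v.maf_panel_1
        row["maf2"] = v.maf_panel_2
        rows.append(row)
    cols = ["variant_id", "gene", "ploidy", *ANNOTATORS, "maf1", "maf2"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
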