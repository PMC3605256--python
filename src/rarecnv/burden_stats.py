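"""Genomewide and compartment-specific rare-CNV burden statistics.

The burden question: do cases carry more rare CNV events (or more affected
base pairs) than controls, genomewide or on a chromosome compartment
(autosomes / X / Y), after adjusting for ancestry covariates?

Provided here:

* per-sample burden summaries (event counts and aneuploid bp),
* Mann-Whitney / Wilcoxon rank-sum comparison of per-sample totals,
* logistic regression of case status on per-sample event count with
  eigenvector covariates, with explicit perfect-separation reporting and
  an optional Firth-penalized fallback,
* cross-cohort combination: inverse-variance fixed or random
  (DerSimonian-Laird) meta-analysis of per-cohort fits, or a single
  pooled fit stratified by cohort indicators,
* locus-by-locus permutation testing with max-statistic (max-T)
  genomewide correction, permuting case/control labels within cohort,
* gene-set burden with platform-stratified permutation (controls for
  probe-coverage differences between array platforms), and
* comparison of precomputed score distributions (e.g. haploinsufficiency
  LOD scores per deletion) between cohorts.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cnv_core import SampleSheet, compartment_of
from .locus_assoc import AssociationResult, CarrierTable, carrier_table

logger = logging.getLogger("rarecnv")

__all__ = [
    "BurdenFit",
    "LocusTestResult",
    "ScoreSet",
    "summarize_burden",
    "ranksum_burden",
    "logistic_burden",
    "combine_cohorts",
    "permutation_locus_test",
    "geneset_burden",
    "compare_score_sets",
]


@dataclass
class BurdenFit:
    """Logistic burden fit (or meta-combination) for the count coefficient."""

    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    n_case: int
    n_control: int
    covariate_betas: np.ndarray = field(default_factory=lambda: np.empty(0))
    separation: bool = False
    method: str = "logistic"
    tau2: float = 0.0  # between-cohort variance (random-effects meta only)


@dataclass
class LocusTestResult:
    locus_id: str
    case_carriers: int
    control_carriers: int
    p_nominal: float
    p_corrected: float


@dataclass
class ScoreSet:
    cohort: str
    status: str
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size and not np.all(np.isfinite(self.scores)):
            raise ValueError("score set contains non-finite values")


# ---------------------------------------------------------------------------
# Per-sample summaries
# ---------------------------------------------------------------------------

def summarize_burden(
    calls: list,
    samples: SampleSheet,
    compartment: str = "genome",
    cnv_class: str | None = None,
) -> pd.DataFrame:
    """Per-sample event counts and aneuploid base pairs.

    One row per sample in the sheet (zero-filled for samples with no
    qualifying events), restricted to ``compartment`` in
    {autosome, X, Y, genome} and, optionally, one CNV class.  Expects
    calls already restricted to the rare stratum of interest.
    Order-invariant: totals do not depend on call order.
    """
    if compartment not in ("autosome", "X", "Y", "genome"):
        raise ValueError(f"unknown compartment {compartment!r}")
    counts = {sid: 0 for sid in samples.sample_ids}
    bps = {sid: 0 for sid in samples.sample_ids}
    for c in calls:
        if cnv_class is not None and c.cnv_class != cnv_class:
            continue
        if compartment != "genome" and compartment_of(c.interval) != compartment:
            continue
        if c.sample_id not in counts:
            continue  # calls for samples outside this sheet are ignored
        counts[c.sample_id] += 1
        bps[c.sample_id] += len(c.interval)
    return pd.DataFrame(
        {
            "sample_id": samples.sample_ids,
            "compartment": compartment,
            "cnv_class": cnv_class or "any",
            "n_events": [counts[s] for s in samples.sample_ids],
            "aneuploid_bp": [bps[s] for s in samples.sample_ids],
        }
    )


def ranksum_burden(case_values, control_values) -> float:
    """Two-sided Mann-Whitney U p-value with tie correction.

    Exact enumeration when both groups have <= 50 observations and no
    ties; normal approximation otherwise.  All-equal degenerate input
    gives p = 1.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.all(x == x[0]) and np.all(y == x[0]):
        return 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size <= 50 and y.size <= 50 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


# ---------------------------------------------------------------------------
# Logistic burden regression
# ---------------------------------------------------------------------------

def _design(counts: np.ndarray, samples: SampleSheet, covariates: bool):
    cols = [np.ones_like(counts, dtype=float), counts.astype(float)]
    names = ["intercept", "count"]
    if covariates:
        for c in samples.covariate_columns:
            v = samples.df[c].to_numpy(dtype=float)
            cols.append(v)
            names.append(c)
    X = np.column_stack(cols)
    # drop collinear columns (keep intercept and count)
    keep = [0, 1]
    for j in range(2, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(j)
        else:
            logger.warning("dropping collinear covariate %s", names[j])
    return X[:, keep], [names[j] for j in keep]


def _firth_logistic(X, y, max_iter=100, tol=1e-8):
    """Firth-penalized logistic regression (Jeffreys-prior score correction)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        XW = X * w[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        h = np.einsum("ij,jk,ik->i", X, info_inv, XW)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, np.sqrt(np.diag(cov))


def logistic_burden(
    counts,
    samples: SampleSheet,
    covariates: bool = True,
    firth_on_separation: bool = False,
) -> BurdenFit:
    """Logistic regression of case status on per-sample event count.

    ``counts`` is an array aligned with the sample sheet or a mapping /
    Series keyed by sample id.  Eigenvector covariate columns of the sheet
    are included when ``covariates`` is True (collinear columns dropped
    with a warning).  The fit is by maximum likelihood (IRLS); Wald CI and
    p-value are reported for the count coefficient.

    Perfect or quasi-separation is detected and flagged on the result
    rather than silently returning a diverged fit; with
    ``firth_on_separation=True`` a Firth-penalized fit is substituted.
    """
    import statsmodels.api as sm

    if isinstance(counts, dict):
        counts = np.array([counts.get(s, 0) for s in samples.sample_ids], dtype=float)
    elif isinstance(counts, pd.Series):
        counts = counts.reindex(samples.sample_ids).fillna(0).to_numpy(dtype=float)
    else:
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != samples.n_samples:
            raise ValueError("counts length does not match sample sheet")

    y = (samples.df["status"] == "case").to_numpy(dtype=float)
    n_case, n_control = samples.n_cases, samples.n_controls
    if n_case == 0 or n_control == 0:
        raise ValueError("need at least one case and one control")
    if np.all(counts == counts[0]):
        raise ValueError("degenerate design: count is constant across samples")

    X, names = _design(counts, samples, covariates)
    j = names.index("count")

    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta = res.params
            se = res.bse
            converged = res.mle_retvals.get("converged", True)
        except Exception:
            converged = False
            beta = np.full(X.shape[1], np.nan)
            se = np.full(X.shape[1], np.nan)
    if (not converged) or (not np.all(np.isfinite(se))) or np.abs(beta[j]) > 15 or se[j] > 50:
        separation = True
        logger.warning("logistic burden fit shows (quasi-)separation or non-convergence")
        if firth_on_separation:
            beta, se = _firth_logistic(X, y)
            separation = False

    b, s = float(beta[j]), float(se[j])
    z = b / s if s > 0 else np.nan
    p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return BurdenFit(
        beta=b,
        se=s,
        or_=math.exp(b) if np.isfinite(b) else np.nan,
        ci_low=math.exp(b - 1.96 * s) if np.isfinite(b + s) else np.nan,
        ci_high=math.exp(b + 1.96 * s) if np.isfinite(b + s) else np.nan,
        p=float(p) if np.isfinite(z) else np.nan,
        n_case=n_case,
        n_control=n_control,
        covariate_betas=np.delete(beta, j),
        separation=separation,
    )


# ---------------------------------------------------------------------------
# Cross-cohort combination
# ---------------------------------------------------------------------------

def combine_cohorts(fits, method: str = "random_iv", data=None) -> BurdenFit:
    """Combine per-cohort burden estimates.

    ``method='fixed_iv'`` / ``'random_iv'``: inverse-variance meta-analysis
    of the per-cohort log-odds betas (DerSimonian-Laird between-cohort
    variance for random effects).  This is the package's approximation to
    a mixed-effects logistic model with cohort as a random factor.

    ``method='pooled_stratified'``: a single logistic fit on the pooled
    data with cohort indicator covariates; pass ``data=(counts, samples)``
    where ``samples`` spans all cohorts.
    """
    if method == "pooled_stratified":
        if data is None:
            raise ValueError("pooled_stratified requires data=(counts, samples)")
        counts, samples = data
        df = samples.df.copy()
        cohorts = sorted(df["cohort"].unique())
        for c in cohorts[1:]:  # first cohort is the reference level
            df[f"cov_cohort_{c}"] = (df["cohort"] == c).astype(float)
        fit = logistic_burden(counts, SampleSheet(df), covariates=True)
        fit.method = "pooled_stratified"
        return fit

    if method not in ("fixed_iv", "random_iv"):
        raise ValueError(f"unknown combination method {method!r}")
    fits = [f for f in fits if np.isfinite(f.beta) and np.isfinite(f.se) and f.se > 0]
    if not fits:
        raise ValueError("no usable cohort fits to combine")
    if len(fits) == 1:
        warnings.warn("single cohort passed through combine_cohorts unchanged")
        out = BurdenFit(**{**fits[0].__dict__})
        out.method = method
        return out

    betas = np.array([f.beta for f in fits])
    variances = np.array([f.se**2 for f in fits])
    w = 1.0 / variances
    beta_fe = float(np.sum(w * betas) / np.sum(w))
    tau2 = 0.0
    if method == "random_iv":
        q = float(np.sum(w * (betas - beta_fe) ** 2))
        df_ = len(fits) - 1
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - df_) / c) if c > 0 else 0.0
        w = 1.0 / (variances + tau2)
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    z = beta / se
    return BurdenFit(
        beta=beta,
        se=se,
        or_=math.exp(beta),
        ci_low=math.exp(beta - 1.96 * se),
        ci_high=math.exp(beta + 1.96 * se),
        p=float(2 * stats.norm.sf(abs(z))),
        n_case=sum(f.n_case for f in fits),
        n_control=sum(f.n_control for f in fits),
        separation=any(f.separation for f in fits),
        method=method,
        tau2=tau2,
    )


# ---------------------------------------------------------------------------
# Permutation locus testing
# ---------------------------------------------------------------------------

def _stratified_permutations(samples: SampleSheet, n_perm: int, rng, stratify: str | None):
    """Yield an (n_perm, n_samples) matrix of permuted case indicators."""
    y = (samples.df["status"] == "case").to_numpy(dtype=np.int8)
    n = y.size
    out = np.empty((n_perm, n), dtype=np.int8)
    if stratify is None:
        for i in range(n_perm):
            out[i] = rng.permutation(y)
        return out
    strata = samples.df[stratify].to_numpy()
    idx_by_stratum = [np.flatnonzero(strata == s) for s in pd.unique(strata)]
    for i in range(n_perm):
        row = np.empty(n, dtype=np.int8)
        for idx in idx_by_stratum:
            row[idx] = y[rng.permutation(idx)]
        out[i] = row
    return out


def permutation_locus_test(
    carrier_matrix: pd.DataFrame,
    samples: SampleSheet,
    n_perm: int = 1000,
    seed: int = 0,
    sides: str = "greater",
    stratify: str | None = "cohort",
) -> list:
    """Locus-by-locus association by case/control label permutation.

    ``carrier_matrix`` is samples x loci (0/1), indexed by sample id.
    The per-locus statistic is the case-carrier count.  Nominal p uses the
    add-one rule (1 + #{perm >= obs}) / (n_perm + 1); the genomewide
    corrected p is max-T: the observed statistic is compared to the
    permutation distribution of the maximum statistic across loci, which
    controls the family-wise error rate.  Labels are permuted within
    cohort by default, respecting platform confounding.

    ``sides='greater'`` tests case enrichment; ``'two_sided'`` uses the
    absolute deviation from the permutation mean.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if carrier_matrix.shape[1] == 0:
        raise ValueError("no loci in carrier matrix")
    X = carrier_matrix.reindex(samples.sample_ids).fillna(0).to_numpy(dtype=np.int8)
    y = (samples.df["status"] == "case").to_numpy(dtype=np.int8)
    obs = y @ X  # case-carrier count per locus
    totals = X.sum(axis=0)

    rng = np.random.default_rng(seed)
    perms = _stratified_permutations(samples, n_perm, rng, stratify)
    perm_stats = perms @ X  # (n_perm, n_loci)

    if sides == "two_sided":
        center = perm_stats.mean(axis=0)
        obs_dev = np.abs(obs - center)
        perm_dev = np.abs(perm_stats - center)
    elif sides == "greater":
        obs_dev = obs.astype(float)
        perm_dev = perm_stats.astype(float)
    else:
        raise ValueError(f"unknown sides {sides!r}")

    nominal = (1 + (perm_dev >= obs_dev).sum(axis=0)) / (n_perm + 1)
    max_per_perm = perm_dev.max(axis=1)
    corrected = (1 + (max_per_perm[:, None] >= obs_dev[None, :]).sum(axis=0)) / (n_perm + 1)
    corrected = np.maximum(corrected, nominal)

    case_ids = set(samples.df.loc[samples.df["status"] == "case", "sample_id"])
    results = []
    for k, locus in enumerate(carrier_matrix.columns):
        carriers = set(carrier_matrix.index[carrier_matrix[locus].astype(bool)])
        results.append(
            LocusTestResult(
                locus_id=str(locus),
                case_carriers=int(obs[k]),
                control_carriers=int(totals[k] - obs[k]),
                p_nominal=float(nominal[k]),
                p_corrected=float(corrected[k]),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Gene-set burden
# ---------------------------------------------------------------------------

def geneset_burden(
    calls: list,
    samples: SampleSheet,
    gene_set: list,
    platform_coverage: dict | None = None,
    cnv_class: str = "loss",
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple:
    """Burden of rare deletions intersecting a gene set.

    Each sample gets an indicator of carrying a qualifying call (of
    ``cnv_class``) that overlaps any interval of the set.  Association is
    tested by permuting labels within platform, which controls for
    coverage differences between array platforms.  Platforms whose probe
    coverage of the set (``platform_coverage``) is zero are excluded with
    a log message.

    Returns ``(CarrierTable, AssociationResult)`` where the result's
    p-values are the stratified permutation p (one- and two-sided) and the
    OR is the Haldane-corrected sample OR.
    """
    if not gene_set:
        raise ValueError("gene set is empty")
    sheet = samples
    if platform_coverage is not None:
        dead = {p for p, cov in platform_coverage.items() if cov == 0}
        if dead:
            logger.info("excluding platforms with no probe coverage of the set: %s", sorted(dead))
            sheet = samples.subset(~samples.df["platform"].isin(dead))

    carriers = set()
    for c in calls:
        if c.cnv_class != cnv_class:
            continue
        if any(c.interval.intersection_length(g) > 0 for g in gene_set):
            carriers.add(c.sample_id)
    carriers &= set(sheet.sample_ids)
    table = carrier_table(carriers, sheet)

    ind = sheet.df["sample_id"].isin(carriers).to_numpy(dtype=np.int8)
    y = (sheet.df["status"] == "case").to_numpy(dtype=np.int8)
    obs = int(ind @ y)
    rng = np.random.default_rng(seed)
    perms = _stratified_permutations(sheet, n_perm, rng, "platform")
    perm_stats = perms @ ind
    p_one = float((1 + (perm_stats >= obs).sum()) / (n_perm + 1))
    center = perm_stats.mean()
    p_two = float((1 + (np.abs(perm_stats - center) >= abs(obs - center)).sum()) / (n_perm + 1))

    a, b, c_, d = (x + 0.5 for x in table.as_tuple())
    result = AssociationResult(
        odds_ratio=(a * d) / (b * c_),
        ci_low=float("nan"),
        ci_high=float("nan"),
        p_two_sided=min(p_two, 1.0),
        p_one_sided=min(p_one, 1.0),
        method="sample",
        ci_method="woolf",
    )
    return table, result


# ---------------------------------------------------------------------------
# Score-set comparison (precomputed haploinsufficiency LODs)
# ---------------------------------------------------------------------------

def compare_score_sets(a: ScoreSet, b: ScoreSet) -> dict:
    """Compare two score distributions (e.g. per-deletion LOD(HI)).

    Returns medians, means and the two-sided rank-sum p.  Cohort panels
    are conventionally ordered by median score, which is what the
    ``median_*`` values support.
    """
    if a.scores.size == 0 or b.scores.size == 0:
        raise ValueError("both score sets must be nonempty")
    if np.array_equal(np.sort(a.scores), np.sort(b.scores)):
        p = 1.0
    else:
        p = ranksum_burden(a.scores, b.scores)
    return {
        "median_a": float(np.median(a.scores)),
        "median_b": float(np.median(b.scores)),
        "mean_a": float(np.mean(a.scores)),
        "mean_b": float(np.mean(b.scores)),
        "p": p,
    }


def order_score_sets(score_sets: list) -> list:
    """Order cohorts by median score (the layout rule for cohort panels)."""
    return sorted(score_sets, key=lambda s: np.median(s.scores))
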