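"""Expression normalization, thresholding, stratification and survival.

Counts are normalized to library size as counts per 20 million reads
(CP20M): CP20M_gs = count_gs / library_size_s * 2e7, so each sample's
normalized column sums to 2e7 when the library size is the column sum.
Genes are kept when at least one sample shows >= 100 raw counts; viral
genomes (each treated as a single gene) are called detected from >= 20
counts.  Marker-gene stratification uses the published CP20M cutoffs
(CDKN2A low < 100 / intermediate 100-1000 / high > 1000; CCNE1 high
from 200; RB1 low < 400 — with an alternative own-cohort scheme at
600 / 100 / 900), and groups are compared with Kaplan-Meier curves and
the Mantel-Cox log-rank test, reporting the O/E-based hazard ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CP20M_SCALE = 2e7
DEFAULT_GENE_MIN_COUNT = 100
DEFAULT_VIRUS_MIN_COUNT = 20


# ---------------------------------------------------------------------------
# Normalization and filters
# ---------------------------------------------------------------------------

def cp20m(
    counts: pd.DataFrame,
    library_size: pd.Series | None = None,
) -> pd.DataFrame:
    """Normalize a genes x samples raw-count matrix to CP20M.

    ``library_size`` defaults to the column sums; a zero library size is
    an error.  Column sums of the result equal 2e7 when the default
    library sizes are used.
    """
    if library_size is None:
        library_size = counts.sum(axis=0)
    else:
        library_size = library_size.reindex(counts.columns)
        if library_size.isna().any():
            raise ValueError("library_size missing for some samples")
    if (library_size <= 0).any():
        bad = library_size[library_size <= 0].index.tolist()
        raise ValueError(f"zero/negative library size for samples {bad}")
    return counts * (CP20M_SCALE / library_size)


def filter_genes(
    counts: pd.DataFrame,
    min_count: int = DEFAULT_GENE_MIN_COUNT,
) -> pd.DataFrame:
    """Keep genes with at least ``min_count`` raw counts in >= 1 sample.

    The boundary is inclusive: a gene whose best sample shows exactly
    ``min_count`` counts is retained.
    """
    keep = counts.max(axis=1) >= min_count
    return counts.loc[keep]


def detect_virus(
    virus_counts: pd.DataFrame,
    min_count: int = DEFAULT_VIRUS_MIN_COUNT,
) -> pd.DataFrame:
    """Call viral genomes detected from a genome x sample count table.

    Each viral genome is quantified as a single gene; a genome is
    detected in a sample iff its (normalized) count is >= ``min_count``,
    a floor that suppresses false-positive hits from stray alignments.
    Returns a boolean table of the same shape.
    """
    return virus_counts >= min_count


# ---------------------------------------------------------------------------
# Marker-gene stratification
# ---------------------------------------------------------------------------

def _strat_cdkn2a_public(x: float) -> str:
    # low < 100; intermediate from 100 to 1000 (both ends in); high > 1000
    if x < 100:
        return "low"
    if x <= 1000:
        return "intermediate"
    return "high"


STRATIFICATION_SCHEMES: dict[str, tuple[str, object, str]] = {
    # name -> (gene, rule, human-readable boundary description)
    "CDKN2A-public": ("CDKN2A", _strat_cdkn2a_public,
                      "low: CP20M < 100; intermediate: 100 <= CP20M <= 1000; "
                      "high: CP20M > 1000"),
    "CCNE1-public": ("CCNE1", lambda x: "high" if x >= 200 else "low",
                     "high: CP20M >= 200; low: CP20M < 200"),
    "RB1-public": ("RB1", lambda x: "low" if x < 400 else "high",
                   "low: CP20M < 400; high: CP20M >= 400"),
    "CDKN2A-own": ("CDKN2A", lambda x: "high" if x >= 600 else "low",
                   "high: CP20M >= 600; low: CP20M < 600"),
    "CCNE1-own": ("CCNE1", lambda x: "high" if x >= 100 else "low",
                  "high: CP20M >= 100; low: CP20M < 100"),
    "RB1-own": ("RB1", lambda x: "low" if x < 900 else "high",
                "low: CP20M < 900; high: CP20M >= 900"),
}


@dataclass
class StrataAssignment:
    gene: str
    scheme: str
    boundaries: str
    groups: pd.Series  # sample -> group label

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.groups.index, "group": self.groups.to_numpy()}
        )


def stratify(
    expression: pd.DataFrame,
    gene: str | None = None,
    scheme: str = "CDKN2A-public",
) -> StrataAssignment:
    """Assign every sample to an expression stratum of a marker gene.

    ``expression`` is a genes x samples CP20M matrix.  ``scheme`` names
    one of the built-in threshold schemes; ``gene`` may override the
    scheme's default gene (e.g. to stratify on an orthologue id).  Every
    sample with an expression value receives exactly one group.
    """
    if scheme not in STRATIFICATION_SCHEMES:
        raise ValueError(
            f"unknown scheme {scheme!r}; valid schemes: "
            f"{sorted(STRATIFICATION_SCHEMES)}"
        )
    default_gene, rule, bounds = STRATIFICATION_SCHEMES[scheme]
    gene = gene or default_gene
    if gene not in expression.index:
        raise ValueError(f"gene {gene!r} absent from the expression matrix")
    values = expression.loc[gene]
    groups = values.map(rule)
    groups.name = "group"
    return StrataAssignment(
        gene=gene, scheme=scheme, boundaries=bounds, groups=groups
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

@dataclass
class LogrankResult:
    """Mantel-Cox log-rank comparison of survival between groups.

    ``observed``/``expected`` are per-group event tallies over the
    pooled event times; for two groups the hazard ratio is the
    O/E-based (O1/E1)/(O2/E2) with a log-scale CI from
    se(log HR) = sqrt(1/E1 + 1/E2).
    """

    groups: list[str]
    observed: np.ndarray
    expected: np.ndarray
    variance: float
    chi_square: float
    p_value: float
    hazard_ratio: float | None
    hr_ci: tuple[float, float] | None
    median_survival: dict[str, float]
    km_curves: dict[str, pd.DataFrame]


def _km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit estimate; rows at each distinct event/censor time."""
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    times = np.unique(time)
    at_risk = len(time)
    surv = 1.0
    rows = [(0.0, 1.0, at_risk)]
    for t in times:
        here = time == t
        d = int(event[here].sum())
        n = int(here.sum())
        if d > 0:
            surv *= 1.0 - d / at_risk
        rows.append((float(t), surv, at_risk - n))
        at_risk -= n
    return pd.DataFrame(rows, columns=["time", "survival", "at_risk"])


def _median_from_curve(curve: pd.DataFrame) -> float:
    below = curve[curve["survival"] <= 0.5]
    if below.empty:
        return float("nan")
    return float(below["time"].iloc[0])


def logrank_tally(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[list[str], np.ndarray, np.ndarray, float]:
    """Observed/expected event counts and hypergeometric variance.

    At every pooled event time t with d_t events among n_t at risk, the
    expected events in group g are d_t * n_gt / n_t; the variance term
    (two groups) is d_t (n_t - d_t) n_1t n_2t / (n_t^2 (n_t - 1)).
    """
    labels = sorted(set(group.tolist()))
    gidx = {g: i for i, g in enumerate(labels)}
    k = len(labels)
    observed = np.zeros(k)
    expected = np.zeros(k)
    variance = 0.0
    event_times = np.unique(time[event == 1])
    for t in event_times:
        at_risk = time >= t
        n_t = int(at_risk.sum())
        d_t = int((event[time == t] == 1).sum())
        if n_t == 0:
            continue
        for g in labels:
            n_gt = int((at_risk & (group == g)).sum())
            d_gt = int(((time == t) & (event == 1) & (group == g)).sum())
            observed[gidx[g]] += d_gt
            expected[gidx[g]] += d_t * n_gt / n_t
        if k == 2 and n_t > 1:
            n_1t = int((at_risk & (group == labels[0])).sum())
            n_2t = n_t - n_1t
            variance += (
                d_t * (n_t - d_t) * n_1t * n_2t / (n_t**2 * (n_t - 1))
            )
    return labels, observed, expected, variance


def km_logrank(surv: pd.DataFrame) -> LogrankResult:
    """Kaplan-Meier curves and Mantel-Cox log-rank test per group.

    ``surv`` columns: ``time_months`` (> 0), ``event`` (1 = death,
    0 = censored), ``group``.  For two groups the chi-square uses the
    variance-standardized form (O1 - E1)^2 / V; for k > 2 groups the
    simpler sum over groups of (O - E)^2 / E.  The hazard ratio is the
    O/E construction; it is undefined (None) when a group has zero
    expected events.
    """
    time = surv["time_months"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    group = surv["group"].to_numpy()
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    labels = sorted(set(group.tolist()))
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    for g in labels:
        if event[group == g].sum() < 1:
            raise ValueError(f"group {g!r} has no events")
    labels, observed, expected, variance = logrank_tally(time, event, group)
    if len(labels) == 2 and variance > 0:
        chi2 = (observed[0] - expected[0]) ** 2 / variance
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = float(np.nansum((observed - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=len(labels) - 1))

    hazard_ratio = None
    hr_ci = None
    if len(labels) == 2 and expected[0] > 0 and expected[1] > 0 \
            and observed[0] > 0 and observed[1] > 0:
        hazard_ratio = (observed[0] / expected[0]) / (observed[1] / expected[1])
        se = np.sqrt(1.0 / expected[0] + 1.0 / expected[1])
        log_hr = np.log(hazard_ratio)
        hr_ci = (
            float(np.exp(log_hr - 1.959963984540054 * se)),
            float(np.exp(log_hr + 1.959963984540054 * se)),
        )
    curves = {}
    medians = {}
    for g in labels:
        m = group == g
        curves[g] = _km_curve(time[m], event[m])
        medians[g] = _median_from_curve(curves[g])
    return LogrankResult(
        groups=labels, observed=observed, expected=expected,
        variance=float(variance), chi_square=float(chi2), p_value=p,
        hazard_ratio=hazard_ratio, hr_ci=hr_ci,
        median_survival=medians, km_curves=curves,
    )


def fisher_exact(table: np.ndarray) -> tuple[float | None, float]:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    Returns (conditional-MLE odds ratio, two-sided p).  A zero row or
    column margin makes any table equally likely: p = 1 and the odds
    ratio is undefined (None).
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of non-negative integer counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return None, 1.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    odds = stats.contingency.odds_ratio(table, kind="conditional")
    return float(odds.statistic), float(p)
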