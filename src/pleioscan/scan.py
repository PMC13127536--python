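"""Rank-based multi-trait subset scan for shared (pleiotropic) variants.

For every variant the scan asks: over all admissible subsets of traits
(every required trait plus at least ``min_optional`` traits from an optional
pool), which subset carries the strongest joint evidence, and how surprising
is it after accounting for the search?

Evidence per trait is the rank-uniform score u = rank(p)/(M+1), computed
within trait across the panel; the subset statistic is the sum of the
subset's u values, whose null distribution for k independent traits is
Irwin-Hall (sum of k Uniform(0,1)), with the exact far-tail closed form
s^k/k! for s <= 1. Optional traits enter the search only when their u passes
the per-trait pre-filter threshold m^(-3/2) (3.9e-4 at the 186-trait
design); required traits bypass the filter.

Because, at fixed subset size, the minimal sum is attained by the smallest
u values, evaluating prefixes of the ascending-sorted candidates is
equivalent to exhaustive enumeration over all admissible subsets. The
selection of the smallest scores makes the raw Irwin-Hall tail
anti-conservative, so each size-j prefix is corrected by the number of
size-j subsets of the pool, q_j = C(|pool|, j) * IH(k_req + j, s_j) — a
union bound, hence a valid p-value — and the reported corrected p-value is
the Bonferroni sum of the evaluated prefixes, min(1, sum_j q_j). Under a
global null with independent traits this is calibrated-to-conservative
(empirically ~alpha at alpha = 1e-3 and below alpha in the far tail).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, comb
from scipy.stats import rankdata

from .sumstats import AlignedPanel, ConfigurationError

#: genome-wide significance threshold for the combined subset p-value
GENOME_WIDE_ALPHA = 5e-8

#: exponent of the per-trait pre-filter threshold m**(-PREFILTER_EXPONENT);
#: 1.5 reproduces the 3.9e-4 threshold of the 186-trait design
PREFILTER_EXPONENT = 1.5


@dataclass(frozen=True)
class ScanConstraint:
    """An admissible-subset design: required traits + optional pool.

    Every evaluated subset contains all ``required`` traits and at least
    ``min_optional`` traits drawn from ``optional_pool``.
    """

    name: str
    required: tuple[str, ...]
    optional_pool: tuple[str, ...]
    min_optional: int = 1

    def __post_init__(self) -> None:
        if set(self.required) & set(self.optional_pool):
            raise ConfigurationError("required and optional pools overlap")
        if not 1 <= self.min_optional <= len(self.optional_pool):
            raise ConfigurationError("min_optional outside [1, |optional_pool|]")

    @property
    def m(self) -> int:
        return len(self.required) + len(self.optional_pool)


@dataclass
class ScanResult:
    """Best admissible subset and corrected p-value for one variant."""

    row: int
    best_subset: tuple[str, ...]
    k: int
    s: float
    p_subset: float
    p_corrected: float
    n_candidates: int


def prefilter_threshold(m: int, exponent: float = PREFILTER_EXPONENT) -> float:
    """Per-trait pre-filter threshold m**(-exponent) for an m-trait design."""
    if m < 2:
        raise ConfigurationError("prefilter threshold needs m >= 2")
    return float(m) ** (-exponent)


def rank_transform(P: np.ndarray) -> np.ndarray:
    """Columnwise rank-uniform scores u = rank/(M+1), average ranks for ties."""
    P = np.asarray(P, float)
    return rankdata(P, axis=0, method="average") / (P.shape[0] + 1)


def irwin_hall_tail(k: int, s: float) -> float:
    """Lower tail P(U_1 + ... + U_k <= s) of the Irwin-Hall distribution.

    Exact: s^k/k! for s <= 1 (evaluated in log space so the far tail does not
    underflow prematurely), the alternating finite sum otherwise, with the
    symmetry P(S <= s) = 1 - P(S <= k - s) used for s > k/2.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if s < 0 or s > k:
        raise ValueError(f"s={s} outside [0, {k}]")
    if s == 0:
        return 0.0
    if s <= 1:
        return float(math.exp(k * math.log(s) - gammaln(k + 1)))
    if s > k / 2:
        return 1.0 - irwin_hall_tail(k, k - s)
    total = 0.0
    for j in range(int(math.floor(s)) + 1):
        total += (-1.0) ** j * comb(k, j) * (s - j) ** k
    return float(min(max(total / math.factorial(k), 0.0), 1.0))


def _log_ih_tail_small(k: np.ndarray, s: np.ndarray) -> np.ndarray:
    """log of s^k/k! elementwise (valid branch: 0 < s <= 1)."""
    with np.errstate(divide="ignore"):
        return k * np.log(s) - gammaln(k + 1)


def best_subset(
    u_row: np.ndarray,
    constraint: ScanConstraint,
    threshold: float,
    trait_order: list[str] | None = None,
) -> ScanResult:
    """Scan one variant's u values for its best admissible trait subset.

    ``u_row`` is ordered as required traits then optional pool (or as
    ``trait_order``). Returns the subset minimizing the size-corrected prefix
    p-value; a null result with p_corrected = 1 when no admissible subset
    passes the filter.
    """
    order = list(trait_order) if trait_order else list(constraint.required) + list(
        constraint.optional_pool
    )
    u = np.asarray(u_row, float)
    pos = {t: i for i, t in enumerate(order)}
    u_req = np.array([u[pos[t]] for t in constraint.required])
    u_opt = np.array([u[pos[t]] for t in constraint.optional_pool])
    opt_names = list(constraint.optional_pool)

    cand = np.flatnonzero(u_opt <= threshold)
    # ascending u, ties broken by trait index (stable sort)
    cand = cand[np.argsort(u_opt[cand], kind="stable")]
    c = len(cand)
    if c < constraint.min_optional:
        return ScanResult(-1, (), 0, np.nan, np.nan, 1.0, 0)

    k_req = len(constraint.required)
    s_req = float(u_req.sum())
    O = len(constraint.optional_pool)
    best_q = np.inf
    best = None
    total_q = 0.0
    n_prefixes = c - constraint.min_optional + 1
    csum = np.cumsum(u_opt[cand])
    for j in range(constraint.min_optional, c + 1):
        s = s_req + float(csum[j - 1])
        k = k_req + j
        p = irwin_hall_tail(k, min(s, k))
        q = min(1.0, p * float(comb(O, j)))
        total_q += q
        if q < best_q:
            best_q = q
            best = (j, s, k, p)
    j, s, k, p = best
    subset = tuple(constraint.required) + tuple(opt_names[i] for i in cand[:j])
    p_corr = min(1.0, total_q)
    return ScanResult(-1, subset, k, s, p, max(p_corr, p), n_prefixes)


def scan(
    panel: AlignedPanel,
    constraint: ScanConstraint,
    alpha: float = GENOME_WIDE_ALPHA,
    threshold: float | None = None,
    stat: str = "rank",
    build_subsets: str = "significant",
) -> pd.DataFrame:
    """Run the subset scan over every variant of an aligned panel.

    ``stat='rank'`` uses rank-uniform scores (default); ``stat='pvalue'``
    uses the raw per-trait p-values as the evidence scores. The per-trait
    pre-filter defaults to m**(-3/2) for the design's m. Returns one row per
    variant: variant key, best subset (semicolon-joined), k, s, p_subset,
    p_corrected, n_candidates, significant. ``build_subsets`` controls for
    which rows the (relatively expensive) subset string is materialized:
    'significant', 'all' or 'none'.
    """
    for t in constraint.required + constraint.optional_pool:
        if t not in panel.traits:
            raise ConfigurationError(f"design trait {t!r} absent from panel")
    if threshold is None:
        threshold = prefilter_threshold(constraint.m)

    order = list(constraint.required) + list(constraint.optional_pool)
    cols = [panel.trait_index(t) for t in order]
    if stat == "rank":
        U = rank_transform(panel.P[:, cols])
    elif stat == "pvalue":
        U = panel.P[:, cols].astype(float)
    else:
        raise ConfigurationError(f"unknown scan statistic {stat!r}")

    R = len(constraint.required)
    O = len(constraint.optional_pool)
    M = U.shape[0]
    s_req = U[:, :R].sum(axis=1) if R else np.zeros(M)
    u_opt = U[:, R:]
    passing = u_opt <= threshold
    counts = passing.sum(axis=1)

    # ascending sort of candidate scores; non-candidates pushed to the end
    masked = np.where(passing, u_opt, np.inf)
    sort_idx = np.argsort(masked, axis=1, kind="stable")
    sorted_u = np.take_along_axis(masked, sort_idx, axis=1)
    csum = np.cumsum(np.where(np.isfinite(sorted_u), sorted_u, 0.0), axis=1)

    j0 = constraint.min_optional
    best_q = np.full(M, np.inf)
    best_j = np.zeros(M, dtype=int)
    best_p = np.full(M, np.nan)
    best_s = np.full(M, np.nan)
    total_q = np.zeros(M)
    any_valid = counts >= j0
    js = np.arange(O + 1)
    log_comb = gammaln(O + 1) - gammaln(js + 1) - gammaln(O - js + 1)

    for j in range(j0, O + 1):
        valid = counts >= j
        if not valid.any():
            break
        s = s_req + csum[:, j - 1]
        k = R + j
        p = np.ones(M)
        small = valid & (s <= 1.0)
        p[small] = np.exp(_log_ih_tail_small(np.float64(k), np.clip(s[small], 1e-320, None)))
        big = valid & (s > 1.0)
        if big.any():
            p[big] = [irwin_hall_tail(k, min(x, k)) for x in s[big]]
        q = np.minimum(1.0, p * math.exp(log_comb[j]))
        total_q[valid] += q[valid]
        better = valid & (q < best_q)
        best_q[better] = q[better]
        best_j[better] = j
        best_p[better] = p[better]
        best_s[better] = s[better]

    p_corr = np.ones(M)
    p_corr[any_valid] = np.minimum(1.0, total_q[any_valid])
    p_corr[any_valid] = np.maximum(p_corr[any_valid], best_p[any_valid])
    n_cand = np.where(any_valid, counts - j0 + 1, 0)
    significant = (p_corr < alpha) & any_valid

    out = panel.variants.copy()
    out["variant"] = (
        out["CHR"].astype(str)
        + ":"
        + out["POS"].astype(str)
        + ":"
        + out["A1"]
        + ":"
        + out["A2"]
    )
    out["k"] = np.where(any_valid, R + best_j, 0)
    out["s"] = best_s
    out["p_subset"] = best_p
    out["p_corrected"] = p_corr
    out["n_candidates"] = n_cand
    out["significant"] = significant

    opt_names = np.array(constraint.optional_pool, dtype=object)
    subsets = np.full(M, "", dtype=object)
    if build_subsets == "all":
        rows = np.flatnonzero(any_valid)
    elif build_subsets == "significant":
        rows = np.flatnonzero(significant)
    else:
        rows = np.array([], dtype=int)
    req_prefix = ";".join(constraint.required)
    for i in rows:
        chosen = opt_names[sort_idx[i, : best_j[i]]]
        parts = ([req_prefix] if req_prefix else []) + list(chosen)
        subsets[i] = ";".join(parts)
    out["best_subset"] = subsets
    return out


# ---------------------------------------------------------------------------
# stage suite


def standard_designs(
    disorders: list[str],
    regions: list[str],
    dimension_groups: dict[str, list[str]] | None = None,
) -> list[ScanConstraint]:
    """The three-stage design suite: per-disorder, per-dimension, all-disorders.

    Stage 1 pairs each disorder with at least one region; stage 2 does the
    same for each disorder dimension (e.g. neurodevelopmental, internalizing,
    schizophrenia/bipolar groupings); stage 3 requires all disorders jointly.
    """
    designs = [
        ScanConstraint(f"disorder:{d}", (d,), tuple(regions)) for d in disorders
    ]
    for gname, members in (dimension_groups or {}).items():
        designs.append(ScanConstraint(f"dimension:{gname}", tuple(members), tuple(regions)))
    designs.append(ScanConstraint("all_disorders", tuple(disorders), tuple(regions)))
    return designs


def run_stage_suite(
    panel: AlignedPanel,
    designs: list[ScanConstraint],
    alpha: float = GENOME_WIDE_ALPHA,
    threshold: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Execute a list of scan designs; one results table per design."""
    return {d.name: scan(panel, d, alpha=alpha, threshold=threshold) for d in designs}
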