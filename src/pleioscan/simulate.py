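"""Synthetic multi-trait GWAS summary statistics with known ground truth.

The generator emulates the study design every downstream stage expects:

* a block of brain-region traits measured on one shared cohort, which makes
  their z-scores correlated even under the null (sample overlap),
* disorder traits measured on disjoint cohorts (no residual correlation),
* point-normal causal architectures per trait, with configurable pairwise
  causal overlap and effect-sign correlation inside the shared component,
* block-diagonal LD with constant within-block genotype correlation r, so
  LD scores have the closed form l = 1 + (b-1) r^2.

Effects are drawn on the standardized-genotype scale, so per-trait
heritability is h2 = M * pi * sigma_beta2 with no allele-frequency
bookkeeping; allele frequencies, sex chromosomes and population structure
are deliberately not modeled. For variant j the genetic signal is
sqrt(n) * (R beta)_j where R is the block LD (correlation) weight matrix,
and the residual across traits is drawn from ``residual_cov``, giving
E[z^2] = 1 + n * pi * sigma_beta2 in the no-LD case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import AlignedPanel, ConfigurationError, P_FLOOR

__all__ = [
    "TraitSpec",
    "OverlapSpec",
    "PlantedVariant",
    "ArchitectureConfig",
    "TruthRecord",
    "simulate_panel",
    "preset_brain_disorder",
    "ld_weight_matrix",
    "ld_r2_matrix",
    "ld_scores_from_blocks",
    "simulate_genotypes",
]


@dataclass(frozen=True)
class TraitSpec:
    trait_id: str
    group: str  # region_area | region_thickness | disorder
    n: float


@dataclass(frozen=True)
class OverlapSpec:
    """Shared causal fraction and within-shared effect correlation for a pair."""

    pi12: float
    rho12: float


@dataclass(frozen=True)
class PlantedVariant:
    """An explicit causal variant with fixed effects, for targeted scenarios."""

    index: int
    betas: dict  # trait_id -> true effect


@dataclass
class ArchitectureConfig:
    M: int
    traits: list[TraitSpec]
    pi: dict
    sigma_beta2: dict
    overlap: dict = field(default_factory=dict)  # (t1, t2) -> OverlapSpec
    residual_cov: np.ndarray | None = None
    ld_blocks: list[tuple[int, float]] | None = None  # (block size, within-block r)
    planted: list[PlantedVariant] = field(default_factory=list)
    seed: int = 0

    @property
    def trait_ids(self) -> list[str]:
        return [t.trait_id for t in self.traits]

    def validate(self) -> None:
        m = len(self.traits)
        ids = self.trait_ids
        if len(set(ids)) != m:
            raise ConfigurationError("duplicate trait ids")
        for t in ids:
            if not 0.0 <= self.pi.get(t, 0.0) <= 1.0:
                raise ConfigurationError(f"pi[{t}] outside [0,1]")
            if self.sigma_beta2.get(t, 0.0) < 0:
                raise ConfigurationError(f"sigma_beta2[{t}] negative")
        for (a, b), ov in self.overlap.items():
            if a not in ids or b not in ids:
                raise ConfigurationError(f"overlap pair ({a},{b}) names unknown trait")
            if ov.pi12 > min(self.pi[a], self.pi[b]) + 1e-12:
                raise ConfigurationError(f"pi12 for ({a},{b}) exceeds min of the pair's pi")
            if abs(ov.rho12) > 1:
                raise ConfigurationError("rho12 outside [-1,1]")
        if self.residual_cov is not None:
            C = np.asarray(self.residual_cov, float)
            if C.shape != (m, m):
                raise ConfigurationError("residual_cov shape mismatch")
            if not np.allclose(np.diag(C), 1.0):
                raise ConfigurationError("residual_cov must have unit diagonal")
            try:
                np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                raise ConfigurationError("residual_cov not positive-definite") from None


@dataclass
class TruthRecord:
    """Generative ground truth used as the oracle in downstream tests."""

    causal_sets: dict  # trait_id -> sorted variant indices
    betas: dict  # trait_id -> length-M effect vector
    shared_sets: dict  # (t1, t2) -> indices causal in both
    sign_concordance: dict  # (t1, t2) -> fraction of shared with equal sign


# ---------------------------------------------------------------------------
# LD helpers (block-diagonal, constant within-block correlation)


def _block_spans(M: int, ld_blocks: list[tuple[int, float]] | None):
    """Tile the (size, r) block pattern over M variants; yields (start, stop, r)."""
    if not ld_blocks:
        ld_blocks = [(1, 0.0)]
    pos = 0
    i = 0
    while pos < M:
        size, r = ld_blocks[i % len(ld_blocks)]
        stop = min(pos + max(int(size), 1), M)
        yield pos, stop, float(r)
        pos = stop
        i += 1


def ld_weight_matrix(M: int, ld_blocks) -> np.ndarray:
    """Dense genotype-correlation matrix R of the block-LD model (small M only)."""
    R = np.eye(M)
    for a, b, r in _block_spans(M, ld_blocks):
        R[a:b, a:b] = r
        np.fill_diagonal(R[a:b, a:b], 1.0)
    return R


def ld_r2_matrix(M: int, ld_blocks) -> np.ndarray:
    """Dense pairwise r^2 matrix of the block-LD model (small M only)."""
    return ld_weight_matrix(M, ld_blocks) ** 2


def ld_scores_from_blocks(M: int, ld_blocks) -> np.ndarray:
    """Closed-form LD scores l_j = 1 + (b-1) r^2 of the block model."""
    ell = np.empty(M)
    for a, b, r in _block_spans(M, ld_blocks):
        ell[a:b] = 1.0 + (b - a - 1) * r * r
    return ell


def _apply_ld(beta: np.ndarray, M: int, ld_blocks) -> np.ndarray:
    """(R beta) without materializing R: within a block, w_i = (1-r) b_i + r sum."""
    out = beta.copy()
    for a, b, r in _block_spans(M, ld_blocks):
        if r != 0.0 and b - a > 1:
            s = beta[a:b].sum()
            out[a:b] = (1.0 - r) * beta[a:b] + r * s
    return out


def simulate_genotypes(
    n_variants: int,
    n_haplotypes: int,
    ld_blocks=None,
    seed: int = 0,
) -> np.ndarray:
    """0/1 haplotype matrix (variants x haplotypes) with block LD.

    A latent Gaussian with within-block correlation sin(pi*r/2) is dichotomized
    at zero, which yields binary correlation r (tetrachoric inversion at a
    50% allele frequency), hence within-block r^2 approx r^2.
    """
    rng = np.random.default_rng(seed)
    G = np.empty((n_variants, n_haplotypes))
    for a, b, r in _block_spans(n_variants, ld_blocks):
        k = b - a
        rho = np.sin(np.pi * min(max(r, 0.0), 1.0) / 2.0)
        shared = rng.standard_normal(n_haplotypes)
        own = rng.standard_normal((k, n_haplotypes))
        G[a:b] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
    return (G > 0.0).astype(np.int8)


# ---------------------------------------------------------------------------
# panel simulation


def _variant_grid(M: int, ld_blocks) -> pd.DataFrame:
    """Synthetic variant coordinates: each LD block sits on its own 2 Mb island
    so distinct blocks are farther apart than any clumping window; chromosomes
    cycle over the 22 autosomes."""
    chrom = np.empty(M, int)
    pos = np.empty(M, int)
    next_pos = {}
    for bi, (a, b, _r) in enumerate(_block_spans(M, ld_blocks)):
        c = bi % 22 + 1
        start = next_pos.get(c, 1_000_000)
        p = start + np.arange(b - a) * 10_000
        chrom[a:b] = c
        pos[a:b] = p
        next_pos[c] = int(p[-1]) + 2_000_000
    return pd.DataFrame({"CHR": chrom, "POS": pos, "A1": "A", "A2": "G"})


def simulate_panel(config: ArchitectureConfig) -> tuple[AlignedPanel, TruthRecord]:
    """Draw an aligned multi-trait z-score panel plus its generative truth.

    Causal indicators are drawn jointly across overlapping pairs so that the
    realized shared fraction honors pi12; within the shared component effects
    are bivariate normal with correlation rho12. Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    M = config.M
    ids = config.trait_ids
    m = len(ids)

    causal: dict[str, np.ndarray] = {t: np.zeros(M, dtype=bool) for t in ids}
    beta: dict[str, np.ndarray] = {t: np.zeros(M) for t in ids}

    # shared causal sets first (joint draws honoring pi12), then per-trait top-up
    for (a, b), ov in config.overlap.items():
        n12 = int(round(M * ov.pi12))
        if n12 == 0:
            continue
        idx = rng.choice(M, size=n12, replace=False)
        causal[a][idx] = True
        causal[b][idx] = True
        sa = np.sqrt(config.sigma_beta2[a])
        sb = np.sqrt(config.sigma_beta2[b])
        x = rng.standard_normal(n12)
        y = rng.standard_normal(n12)
        beta[a][idx] = sa * x
        beta[b][idx] = sb * (ov.rho12 * x + np.sqrt(1.0 - ov.rho12**2) * y)

    for t in ids:
        total = int(round(M * config.pi.get(t, 0.0)))
        extra = total - int(causal[t].sum())
        if extra > 0:
            pool = np.flatnonzero(~causal[t])
            idx = rng.choice(pool, size=min(extra, len(pool)), replace=False)
            causal[t][idx] = True
            beta[t][idx] = rng.standard_normal(len(idx)) * np.sqrt(config.sigma_beta2[t])

    for pv in config.planted:
        for t, b_val in pv.betas.items():
            causal[t][pv.index] = True
            beta[t][pv.index] = b_val

    # genetic signal through LD, plus correlated residual across traits
    n_by_trait = np.array([t.n for t in config.traits], float)
    signal = np.empty((M, m))
    for j, t in enumerate(ids):
        signal[:, j] = np.sqrt(n_by_trait[j]) * _apply_ld(beta[t], M, config.ld_blocks)
    C = np.eye(m) if config.residual_cov is None else np.asarray(config.residual_cov, float)
    Lc = np.linalg.cholesky(C)
    resid = rng.standard_normal((M, m)) @ Lc.T
    Z = signal + resid
    P = np.clip(2.0 * stats.norm.sf(np.abs(Z)), P_FLOOR, 1.0)

    panel = AlignedPanel(
        traits=list(ids),
        variants=_variant_grid(M, config.ld_blocks),
        Z=Z,
        P=P,
        N=n_by_trait,
        group_labels={t.trait_id: t.group for t in config.traits},
    )

    shared_sets = {}
    concord = {}
    # all unordered pairs: incidental co-causality is ground truth too
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            both = np.flatnonzero(causal[a] & causal[b])
            if len(both) == 0 and (a, b) not in config.overlap:
                continue
            shared_sets[(a, b)] = both
            if len(both):
                agree = np.sign(beta[a][both]) == np.sign(beta[b][both])
                concord[(a, b)] = float(np.mean(agree))
            else:
                concord[(a, b)] = np.nan
    truth = TruthRecord(
        causal_sets={t: np.flatnonzero(causal[t]) for t in ids},
        betas=beta,
        shared_sets=shared_sets,
        sign_concordance=concord,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# study-design preset


def preset_brain_disorder(
    R: int = 20,
    D: int = 4,
    M: int = 20_000,
    n_region: float = 35_000,
    n_disorder: float = 100_000,
    region_r: float = 0.3,
    pi_region: float = 1e-3,
    pi_disorder: float = 1e-3,
    sigma_beta2_region: float = 1e-4,
    sigma_beta2_disorder: float = 5e-5,
    ld_blocks: list[tuple[int, float]] | None = None,
    overlap: dict | None = None,
    planted: list[PlantedVariant] | None = None,
    seed: int = 0,
) -> ArchitectureConfig:
    """Small-scale template of the brain-region / disorder study design.

    R region traits share one cohort, inducing a dense residual z-correlation
    block (off-diagonal ``region_r``); D disorder traits come from disjoint
    cohorts and are residually uncorrelated with everything. The full-scale
    design is R=180, D=6 (m=186); the default is scaled down so whole-pipeline
    runs stay fast.
    """
    regions = [TraitSpec(f"region{r + 1:03d}", "region_area", n_region) for r in range(R)]
    disorders = [TraitSpec(f"disorder{d + 1}", "disorder", n_disorder) for d in range(D)]
    traits = disorders + regions
    m = len(traits)
    C = np.eye(m)
    reg0 = D
    C[reg0:, reg0:] = region_r
    np.fill_diagonal(C, 1.0)
    pi = {t.trait_id: (pi_disorder if t.group == "disorder" else pi_region) for t in traits}
    s2 = {
        t.trait_id: (sigma_beta2_disorder if t.group == "disorder" else sigma_beta2_region)
        for t in traits
    }
    return ArchitectureConfig(
        M=M,
        traits=traits,
        pi=pi,
        sigma_beta2=s2,
        overlap=dict(overlap or {}),
        residual_cov=C,
        ld_blocks=ld_blocks,
        planted=list(planted or []),
        seed=seed,
    )
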