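"""Cross-trait null covariance estimation and z-score whitening.

GWAS computed on one shared cohort (the brain-region traits) have correlated
z-scores even for purely null variants. The scan assumes independent
evidence across traits, so the region block is decorrelated first: estimate
the m x m z covariance C from near-null variants, factor C = L L^T, and
replace each variant's z vector by L^{-1} z. Under the null the transformed
scores have identity covariance; p-values are recomputed from the
transformed z. Traits from disjoint cohorts (the disorders) are left
untouched by default.

The transform depends on trait order (a Cholesky factor is triangular); the
order is fixed and recorded in the model. A symmetric inverse-square-root
(ZCA) operator is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .sumstats import AlignedPanel, ConfigurationError, P_FLOOR

logger = logging.getLogger("pleioscan")


class EstimationError(ValueError):
    """Too few variants pass the near-null mask to estimate the covariance."""


@dataclass
class WhiteningModel:
    traits: list[str]
    C: np.ndarray  # estimated z covariance, m x m, symmetric PD
    L: np.ndarray  # lower-triangular Cholesky factor, C = L L^T
    estimation_mask: np.ndarray  # which panel variants fed the estimate
    shrinkage_used: float = 0.0

    def __post_init__(self) -> None:
        if not np.allclose(self.C, self.C.T):
            raise ValueError("covariance not symmetric")
        if not np.allclose(self.L @ self.L.T, self.C, atol=1e-10):
            raise ValueError("Cholesky factor does not reconstruct C")


def estimate_covariance(
    panel: AlignedPanel,
    trait_subset: list[str] | None = None,
    null_z_cap: float = 2.0,
    shrinkage_step: float = 0.05,
    min_variants: int = 500,
) -> WhiteningModel:
    """Estimate the cross-trait z covariance from near-null variants.

    Variants where every included trait has |z| < ``null_z_cap`` form the
    estimation mask (signal would otherwise inflate the correlations; pass
    ``np.inf`` to disable the cap). If the sample covariance is not positive
    definite it is shrunk toward the identity in steps of ``shrinkage_step``
    until it is, with a logged warning.
    """
    traits = list(trait_subset) if trait_subset is not None else list(panel.traits)
    idx = [panel.trait_index(t) for t in traits]
    Zs = panel.Z[:, idx]
    mask = np.all(np.abs(Zs) < null_z_cap, axis=1)
    if int(mask.sum()) < min_variants:
        raise EstimationError(
            f"only {int(mask.sum())} variants pass |z| < {null_z_cap}; "
            "increase null_z_cap or supply more variants"
        )
    C = np.cov(Zs[mask], rowvar=False)
    C = np.atleast_2d(C)
    w = 0.0
    # well-conditioned positive definiteness, not merely a nonzero pivot:
    # near-duplicate traits must trigger shrinkage
    min_rel_eig = 1e-8
    while True:
        C_try = (1.0 - w) * C + w * np.eye(len(traits))
        eigs = np.linalg.eigvalsh(C_try)
        if eigs[0] > min_rel_eig * eigs[-1]:
            L = np.linalg.cholesky(C_try)
            break
        w += shrinkage_step
        if w > 1.0:
            raise EstimationError("covariance not repairable by shrinkage") from None
    if w > 0.0:
        logger.warning(
            "z covariance not positive-definite; shrunk toward identity (w=%.2f)", w
        )
    return WhiteningModel(traits=traits, C=C_try, L=L, estimation_mask=mask, shrinkage_used=w)


def whiten(
    panel: AlignedPanel,
    model: WhiteningModel,
    operator: str = "cholesky",
    recompute_p: bool = True,
) -> AlignedPanel:
    """Apply the whitening transform to the modeled traits of a panel.

    ``operator='cholesky'`` maps z -> L^{-1} z (triangular, order-dependent);
    ``operator='zca'`` maps z -> C^{-1/2} z (symmetric). Traits not covered by
    the model pass through unchanged. P-values of transformed traits are
    recomputed as two-sided normal tails.
    """
    missing = [t for t in model.traits if t not in panel.traits]
    if missing:
        raise ConfigurationError(f"model traits absent from panel: {missing}")
    idx = [panel.trait_index(t) for t in model.traits]
    Z = panel.Z.copy()
    if operator == "cholesky":
        Zt = linalg.solve_triangular(model.L, Z[:, idx].T, lower=True).T
    elif operator == "zca":
        vals, vecs = np.linalg.eigh(model.C)
        inv_sqrt = (vecs * (1.0 / np.sqrt(vals))) @ vecs.T
        Zt = Z[:, idx] @ inv_sqrt.T
    else:
        raise ConfigurationError(f"unknown whitening operator {operator!r}")
    Z[:, idx] = Zt
    P = panel.P.copy()
    if recompute_p:
        P[:, idx] = np.clip(2.0 * stats.norm.sf(np.abs(Zt)), P_FLOOR, 1.0)
    return AlignedPanel(
        traits=list(panel.traits),
        variants=panel.variants.copy(),
        Z=Z,
        P=P,
        N=panel.N.copy(),
        group_labels=dict(panel.group_labels),
    )


def decorrelate_regions(
    panel: AlignedPanel,
    region_groups: tuple[str, ...] = ("region_area", "region_thickness"),
    null_z_cap: float = 2.0,
    operator: str = "cholesky",
) -> tuple[AlignedPanel, WhiteningModel]:
    """Whiten the same-cohort region block, leaving disorder traits raw.

    Convenience wrapper for the standard pipeline: the region traits share a
    cohort and need decorrelation, the disorders come from disjoint samples
    and do not.
    """
    regions = panel.traits_in_group(*region_groups)
    if len(regions) < 2:
        raise ConfigurationError("need at least two region traits to decorrelate")
    model = estimate_covariance(panel, trait_subset=regions, null_z_cap=null_z_cap)
    return whiten(panel, model, operator=operator), model
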