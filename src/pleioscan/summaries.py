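"""Locus-level pleiotropy summaries: region counts, direction profiles,
consistency classification and sign-concordance tables.

Two selection modes decide which brain regions "belong" to a locus:

* ``decorrelated_gwas`` — regions whose per-trait p-value in the whitened
  panel reaches genome-wide significance (p < 5e-8) at the lead SNP;
* ``sumrank_selected`` — regions appearing in the scan's best subset for the
  lead SNP, provided the corrected scan p-value is significant.

Signed effects are always read from the ORIGINAL (pre-whitening) panel, so
direction statements refer to the per-trait GWAS effect scale. A locus is
``consistent_positive``/``consistent_negative`` when every selected region
effect shares one sign, ``divergent`` when at least one strictly positive
and one strictly negative effect co-occur; exact zeros carry no direction
and are excluded.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .clumping import Locus, loci_table
from .scan import GENOME_WIDE_ALPHA
from .sumstats import AlignedPanel, VariantKey

logger = logging.getLogger("pleioscan")

MODES = ("decorrelated_gwas", "sumrank_selected")


@dataclass
class DirectionProfile:
    lead: VariantKey
    mode: str
    region_effects: dict  # region trait -> signed effect
    disorder_effects: dict  # disorder trait -> signed effect
    classification: str  # consistent_positive | consistent_negative | divergent | undetermined
    n_regions: int


@dataclass
class RegionCountSummary:
    label: str
    counts: list[int]
    median: float
    iqr: tuple[float, float]
    density: dict  # count -> fraction of SNPs

    @classmethod
    def from_counts(cls, label: str, counts: list[int]) -> "RegionCountSummary":
        if not counts:
            return cls(label, [], np.nan, (np.nan, np.nan), {})
        arr = np.asarray(counts, float)
        # quartiles by linear interpolation between order statistics
        q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
        vals, freq = np.unique(arr.astype(int), return_counts=True)
        dens = {int(v): float(f) / len(arr) for v, f in zip(vals, freq)}
        return cls(label, [int(c) for c in counts], float(med), (float(q1), float(q3)), dens)


@dataclass
class ConcordanceResult:
    fraction: float
    n_pairs: int
    n_concordant: int
    n_ties_excluded: int
    ci95: tuple[float, float]


# ---------------------------------------------------------------------------
# region selection per variant


def _variant_row(panel: AlignedPanel, key: VariantKey) -> int:
    v = panel.variants
    hit = np.flatnonzero(
        (v["CHR"].to_numpy() == key.chrom)
        & (v["POS"].to_numpy() == key.pos)
        & (v["A1"].to_numpy() == key.a1)
        & (v["A2"].to_numpy() == key.a2)
    )
    if len(hit) == 0:
        raise KeyError(f"variant {key} not in panel")
    return int(hit[0])


def _scan_row(scan_results: pd.DataFrame, key: VariantKey) -> pd.Series | None:
    hit = scan_results[
        (scan_results["CHR"] == key.chrom)
        & (scan_results["POS"] == key.pos)
        & (scan_results["A1"] == key.a1)
        & (scan_results["A2"] == key.a2)
    ]
    return None if hit.empty else hit.iloc[0]


def select_regions(
    key: VariantKey,
    mode: str,
    region_traits: list[str],
    decorrelated_panel: AlignedPanel | None = None,
    scan_results: pd.DataFrame | None = None,
    alpha: float = GENOME_WIDE_ALPHA,
) -> list[str]:
    """Regions attributed to a variant under the chosen threshold rule."""
    if mode == "decorrelated_gwas":
        if decorrelated_panel is None:
            raise ValueError("decorrelated_gwas mode needs the whitened panel")
        row = _variant_row(decorrelated_panel, key)
        cols = [decorrelated_panel.trait_index(t) for t in region_traits]
        p = decorrelated_panel.P[row, cols]
        return [t for t, pv in zip(region_traits, p) if pv < alpha]
    if mode == "sumrank_selected":
        if scan_results is None:
            raise ValueError("sumrank_selected mode needs scan results")
        sr = _scan_row(scan_results, key)
        if sr is None or not sr["significant"] or float(sr["p_corrected"]) >= alpha:
            return []
        subset = str(sr["best_subset"]).split(";") if sr["best_subset"] else []
        return [t for t in subset if t in set(region_traits)]
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


# ---------------------------------------------------------------------------
# operations


def region_count_summary(
    loci: list[Locus],
    mode: str,
    region_traits: list[str],
    label: str = "",
    decorrelated_panel: AlignedPanel | None = None,
    scan_results: pd.DataFrame | None = None,
    alpha: float = GENOME_WIDE_ALPHA,
    per: str = "independent",
) -> RegionCountSummary:
    """Per-SNP counts of associated regions, with median/IQR and density.

    ``per='independent'`` counts regions for every independent significant
    SNP; ``per='lead'`` for locus leads only. An empty locus list yields an
    empty summary (no error).
    """
    snps: list[VariantKey] = []
    for loc in loci:
        snps.extend(loc.independent_snps if per == "independent" else [loc.lead])
    counts = [
        len(
            select_regions(
                v,
                mode,
                region_traits,
                decorrelated_panel=decorrelated_panel,
                scan_results=scan_results,
                alpha=alpha,
            )
        )
        for v in snps
    ]
    return RegionCountSummary.from_counts(label or mode, counts)


def direction_profile(
    lead: VariantKey,
    effect_panel: AlignedPanel,
    mode: str,
    region_traits: list[str],
    disorder_traits: list[str],
    decorrelated_panel: AlignedPanel | None = None,
    scan_results: pd.DataFrame | None = None,
    alpha: float = GENOME_WIDE_ALPHA,
) -> DirectionProfile:
    """Signed effect profile of a lead SNP across its selected regions.

    Effects come from ``effect_panel`` (the original, pre-whitening panel;
    z shares the sign of beta). Regions are selected by ``mode``; a region
    missing from the effect panel's traits is omitted with a warning.
    """
    selected = select_regions(
        lead,
        mode,
        region_traits,
        decorrelated_panel=decorrelated_panel,
        scan_results=scan_results,
        alpha=alpha,
    )
    row = _variant_row(effect_panel, lead)
    region_effects = {}
    for t in selected:
        if t not in effect_panel.traits:
            logger.warning("region %s missing from effect panel; omitted", t)
            continue
        region_effects[t] = float(effect_panel.Z[row, effect_panel.trait_index(t)])
    disorder_effects = {
        t: float(effect_panel.Z[row, effect_panel.trait_index(t)])
        for t in disorder_traits
        if t in effect_panel.traits
    }
    signs = {np.sign(v) for v in region_effects.values() if v != 0.0}
    if not signs:
        cls = "undetermined"
    elif signs == {1.0}:
        cls = "consistent_positive"
    elif signs == {-1.0}:
        cls = "consistent_negative"
    else:
        cls = "divergent"
    return DirectionProfile(
        lead=lead,
        mode=mode,
        region_effects=region_effects,
        disorder_effects=disorder_effects,
        classification=cls,
        n_regions=len(region_effects),
    )


def sign_concordance(
    signs_a: np.ndarray, signs_b: np.ndarray, ci_method: str = "beta"
) -> ConcordanceResult:
    """Fraction of pairs with agreeing signs, with a binomial 95% interval.

    Zero effects are ties: excluded from the denominator and counted.
    Interval: Clopper-Pearson by default.
    """
    a = np.sign(np.asarray(signs_a, float))
    b = np.sign(np.asarray(signs_b, float))
    ties = (a == 0) | (b == 0)
    n_ties = int(ties.sum())
    if n_ties:
        logger.info("excluding %d zero-effect (tied) pairs from concordance", n_ties)
    a, b = a[~ties], b[~ties]
    n = len(a)
    if n == 0:
        return ConcordanceResult(np.nan, 0, 0, n_ties, (np.nan, np.nan))
    k = int((a == b).sum())
    lo, hi = proportion_confint(k, n, alpha=0.05, method=ci_method)
    return ConcordanceResult(k / n, n, k, n_ties, (float(lo), float(hi)))


def shared_locus_concordance(
    loci: list[Locus],
    effect_panel: AlignedPanel,
    disorder_trait: str,
    region_traits: list[str],
    mode: str = "sumrank_selected",
    decorrelated_panel: AlignedPanel | None = None,
    scan_results: pd.DataFrame | None = None,
    alpha: float = GENOME_WIDE_ALPHA,
) -> ConcordanceResult:
    """Disorder-vs-region effect-sign concordance over shared loci.

    For each locus lead and each region selected for it, the pair
    (sign of disorder effect, sign of region effect) contributes one
    observation; the aggregate fraction is reported with its binomial
    interval. 0.5 means no directional pattern.
    """
    sa, sb = [], []
    for loc in loci:
        row = _variant_row(effect_panel, loc.lead)
        d_eff = float(effect_panel.Z[row, effect_panel.trait_index(disorder_trait)])
        for t in select_regions(
            loc.lead,
            mode,
            region_traits,
            decorrelated_panel=decorrelated_panel,
            scan_results=scan_results,
            alpha=alpha,
        ):
            sa.append(d_eff)
            sb.append(float(effect_panel.Z[row, effect_panel.trait_index(t)]))
    return sign_concordance(np.asarray(sa), np.asarray(sb))


# ---------------------------------------------------------------------------
# report bundle


def build_report(
    outdir: str | Path,
    stage_results: dict[str, pd.DataFrame],
    stage_loci: dict[str, list[Locus]],
    summaries: dict[str, RegionCountSummary] | None = None,
    profiles: dict[str, list[DirectionProfile]] | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Write per-design result tables, locus tables, count densities and a
    run manifest (versions, seed, config hash) into ``outdir``.

    Returns the manifest dict (also written as report.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in stage_results.items():
        path = outdir / f"scan_{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        files[f"scan_{name}"] = path.name
    for name, loci in stage_loci.items():
        path = outdir / f"loci_{name}.tsv"
        loci_table(loci).to_csv(path, sep="\t", index=False)
        files[f"loci_{name}"] = path.name
    for name, summ in (summaries or {}).items():
        path = outdir / f"region_counts_{name}.tsv"
        pd.DataFrame(
            {"n_regions": list(summ.density), "density": list(summ.density.values())}
        ).to_csv(path, sep="\t", index=False)
        files[f"region_counts_{name}"] = path.name
    prof_rows = []
    for name, plist in (profiles or {}).items():
        for p in plist:
            prof_rows.append(
                {
                    "analysis": name,
                    "lead": str(p.lead),
                    "mode": p.mode,
                    "classification": p.classification,
                    "n_regions": p.n_regions,
                    "region_effects": json.dumps(p.region_effects, sort_keys=True),
                    "disorder_effects": json.dumps(p.disorder_effects, sort_keys=True),
                }
            )
    if profiles is not None:
        path = outdir / "direction_profiles.tsv"
        pd.DataFrame(
            prof_rows,
            columns=[
                "analysis",
                "lead",
                "mode",
                "classification",
                "n_regions",
                "region_effects",
                "disorder_effects",
            ],
        ).to_csv(path, sep="\t", index=False)
        files["direction_profiles"] = path.name

    import pleioscan

    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "pleioscan_version": pleioscan.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_designs": len(stage_results),
        "n_loci": {name: len(l) for name, l in stage_loci.items()},
        "files": files,
    }
    (outdir / "report.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def plot_region_count_density(summary: RegionCountSummary, path: str | Path) -> None:
    """Optional plotting hook: density of per-SNP region counts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    xs = sorted(summary.density)
    ax.bar(xs, [summary.density[x] for x in xs], width=0.85)
    ax.axvline(summary.median, color="crimson", lw=1, label=f"median = {summary.median:g}")
    ax.set_xlabel("associated brain regions per SNP")
    ax.set_ylabel("density")
    ax.set_title(summary.label)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
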