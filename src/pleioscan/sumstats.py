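"""Reading, harmonizing and aligning per-trait GWAS summary statistics.

Summary statistics arrive as delimited text with one row per variant
(chromosome, position, effect/other allele, effect size, standard error,
p-value, sample size). Traits are intersected on the shared variant set and
assembled into an aligned z-score / p-value matrix, the common currency of
every downstream stage.

Conventions: autosomes 1-22 only, biallelic SNPs only (single-base A/C/G/T
alleles), 1-based positions, inclusive region-exclusion windows. Effects are
on the A1 (effect-allele) scale; odds ratios are converted by natural log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("pleioscan")

#: smallest representable p-value; inputs of 0 are clipped here so that
#: log-space statistics stay finite downstream
P_FLOOR = 1e-300

#: canonical column order of the tab-separated summary-statistics format
STANDARD_COLUMNS = ("SNP", "CHR", "POS", "A1", "A2", "BETA", "SE", "P", "N")

_VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class ConfigurationError(ValueError):
    """A column map, trait list or parameter does not match the data."""


class InputError(ValueError):
    """The input rows themselves are unusable (e.g. nothing valid remains)."""


class VariantKey(NamedTuple):
    """Biallelic autosomal variant identity: chromosome, position, alleles."""

    chrom: int
    pos: int
    a1: str
    a2: str

    def __str__(self) -> str:  # CHR:POS:A1:A2, the conventional identifier
        return f"{self.chrom}:{self.pos}:{self.a1}:{self.a2}"


@dataclass
class SummaryStatsTable:
    """One trait's GWAS summary statistics, validated and deduplicated.

    ``df`` holds the standard columns; ``n_dropped`` counts rows rejected
    during reading and ``n_flagged_p`` counts rows whose stated p-value is
    inconsistent with ``2*Phi(-|beta/se|)`` beyond tolerance (kept, flagged).
    """

    trait_id: str
    df: pd.DataFrame
    n_dropped: int = 0
    n_flagged_p: int = 0

    @property
    def M(self) -> int:
        return len(self.df)

    def keys(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.df[["CHR", "POS", "A1", "A2"]])


@dataclass
class AlignedPanel:
    """Variant-aligned multi-trait z-score and p-value matrices.

    Intersection semantics: every (variant, trait) cell is filled. ``variants``
    is a DataFrame with CHR/POS/A1/A2 sorted deterministically; ``Z`` and ``P``
    are M x m arrays in that variant order and ``traits`` column order.
    """

    traits: list[str]
    variants: pd.DataFrame
    Z: np.ndarray
    P: np.ndarray
    N: np.ndarray
    group_labels: dict[str, str] = field(default_factory=dict)

    @property
    def M(self) -> int:
        return len(self.variants)

    @property
    def m(self) -> int:
        return len(self.traits)

    def trait_index(self, trait_id: str) -> int:
        try:
            return self.traits.index(trait_id)
        except ValueError:
            raise ConfigurationError(f"trait {trait_id!r} not in panel") from None

    def traits_in_group(self, *groups: str) -> list[str]:
        return [t for t in self.traits if self.group_labels.get(t) in groups]

    def variant_keys(self) -> list[VariantKey]:
        return [
            VariantKey(int(c), int(p), a1, a2)
            for c, p, a1, a2 in self.variants.itertuples(index=False)
        ]

    def subset_variants(self, mask: np.ndarray) -> "AlignedPanel":
        mask = np.asarray(mask, dtype=bool)
        return AlignedPanel(
            traits=list(self.traits),
            variants=self.variants.loc[mask].reset_index(drop=True),
            Z=self.Z[mask],
            P=self.P[mask],
            N=self.N.copy(),
            group_labels=dict(self.group_labels),
        )

    # -- serialization: one wide TSV plus a JSON sidecar of trait metadata --

    def save(self, path: str | Path) -> None:
        path = Path(path)
        wide = self.variants.copy()
        for i, t in enumerate(self.traits):
            wide[f"z_{t}"] = self.Z[:, i]
        for i, t in enumerate(self.traits):
            wide[f"p_{t}"] = self.P[:, i]
        wide.to_csv(path, sep="\t", index=False)
        meta = {
            "traits": self.traits,
            "N": [float(n) for n in self.N],
            "group_labels": self.group_labels,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "AlignedPanel":
        path = Path(path)
        wide = pd.read_csv(path, sep="\t")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        traits = meta["traits"]
        Z = wide[[f"z_{t}" for t in traits]].to_numpy(float)
        P = wide[[f"p_{t}" for t in traits]].to_numpy(float)
        return cls(
            traits=traits,
            variants=wide[["CHR", "POS", "A1", "A2"]].copy(),
            Z=Z,
            P=P,
            N=np.asarray(meta["N"], float),
            group_labels=dict(meta["group_labels"]),
        )


# ---------------------------------------------------------------------------
# reading


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR, 1.0)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    sep: str = "\t",
    p_floor: float = P_FLOOR,
) -> SummaryStatsTable:
    """Read one trait's summary statistics from delimited text.

    ``column_map`` maps standard names (SNP, CHR, POS, A1, A2, BETA, SE, P, N)
    to the file's header names; ``OR`` may be mapped instead of ``BETA`` (odds
    ratios are log-converted). A missing P column is recomputed as the
    two-sided normal tail of beta/se. Rows with missing or non-finite
    beta/se/p, se<=0, non-autosomal chromosomes, non-SNP or identical alleles,
    and duplicate variant keys are dropped with a logged count.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep)
    cmap = dict(column_map or {})

    def col(name: str) -> str | None:
        target = cmap.get(name, name)
        return target if target in raw.columns else None

    required = ["CHR", "POS", "A1", "A2", "SE", "N"]
    missing = [c for c in required if col(c) is None]
    has_beta, has_or = col("BETA") is not None, col("OR") is not None
    if not has_beta and not has_or:
        missing.append("BETA")
    if missing:
        raise ConfigurationError(
            f"{path.name}: required column(s) {missing} not found "
            f"(header: {list(raw.columns)})"
        )

    df = pd.DataFrame(
        {
            "CHR": pd.to_numeric(raw[col("CHR")], errors="coerce"),
            "POS": pd.to_numeric(raw[col("POS")], errors="coerce"),
            "A1": raw[col("A1")].astype(str).str.upper(),
            "A2": raw[col("A2")].astype(str).str.upper(),
            "SE": pd.to_numeric(raw[col("SE")], errors="coerce"),
            "N": pd.to_numeric(raw[col("N")], errors="coerce"),
        }
    )
    if has_beta:
        df["BETA"] = pd.to_numeric(raw[col("BETA")], errors="coerce")
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            df["BETA"] = np.log(pd.to_numeric(raw[col("OR")], errors="coerce"))
    if col("P") is not None:
        df["P"] = pd.to_numeric(raw[col("P")], errors="coerce")
    else:
        df["P"] = _two_sided_p(df["BETA"].to_numpy() / df["SE"].to_numpy())
    df["SNP"] = (
        raw[col("SNP")].astype(str)
        if col("SNP") is not None
        else df["CHR"].astype("Int64").astype(str)
        + ":"
        + df["POS"].astype("Int64").astype(str)
        + ":"
        + df["A1"]
        + ":"
        + df["A2"]
    )

    n0 = len(df)
    ok = (
        np.isfinite(df["BETA"])
        & np.isfinite(df["SE"])
        & (df["SE"] > 0)
        & np.isfinite(df["P"])
        & np.isfinite(df["N"])
        & (df["N"] > 0)
        & df["CHR"].isin(range(1, 23))
        & (df["POS"] > 0)
        & df["A1"].isin(_VALID_ALLELES)
        & df["A2"].isin(_VALID_ALLELES)
        & (df["A1"] != df["A2"])
    )
    df = df.loc[ok].copy()
    df["CHR"] = df["CHR"].astype(int)
    df["POS"] = df["POS"].astype(int)
    df = df.drop_duplicates(subset=["CHR", "POS", "A1", "A2"], keep="first")
    n_dropped = n0 - len(df)
    if len(df) == 0:
        raise InputError(f"{path.name}: no valid summary-statistics rows")
    if n_dropped:
        logger.info("%s: dropped %d/%d invalid rows", path.name, n_dropped, n0)

    df["P"] = df["P"].clip(lower=p_floor, upper=1.0)
    p_check = _two_sided_p(df["BETA"].to_numpy() / df["SE"].to_numpy())
    flagged = np.abs(p_check - df["P"].to_numpy()) >= 1e-6
    # far tails underflow the comparison; only flag where the stated p is
    # large enough for the normal tail to be meaningfully resolvable
    flagged &= df["P"].to_numpy() > 1e-250
    n_flagged = int(flagged.sum())
    if n_flagged:
        logger.warning(
            "%s: %d rows where P disagrees with 2*Phi(-|beta/se|)", path.name, n_flagged
        )
    df = df[list(STANDARD_COLUMNS)].reset_index(drop=True)
    tid = trait_id if trait_id is not None else path.stem
    return SummaryStatsTable(tid, df, n_dropped=n_dropped, n_flagged_p=n_flagged)


def write_sumstats(table: SummaryStatsTable, path: str | Path, sep: str = "\t") -> None:
    table.df[list(STANDARD_COLUMNS)].to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# harmonization and alignment


def harmonize_alleles(
    tables: Sequence[SummaryStatsTable],
    reference: str,
    drop_ambiguous: bool = False,
) -> list[SummaryStatsTable]:
    """Align allele coding of all tables to the reference trait.

    For each (CHR, POS) present in the reference, a table coding the same
    variant with swapped A1/A2 gets its alleles swapped and its effect sign
    flipped; an incompatible allele pair is dropped. Strand-ambiguous A/T and
    C/G variants are dropped from every table when ``drop_ambiguous`` is set.
    Variants absent from the reference pass through untouched (the later
    intersection removes them). Idempotent by construction.
    """
    if len(tables) < 2:
        raise ConfigurationError("harmonization needs at least two tables")
    by_id = {t.trait_id: t for t in tables}
    if reference not in by_id:
        raise ConfigurationError(f"reference trait {reference!r} not among tables")

    def strip_ambiguous(df: pd.DataFrame) -> pd.DataFrame:
        amb = [(a, b) in _AMBIGUOUS_PAIRS for a, b in zip(df["A1"], df["A2"])]
        n = int(np.sum(amb))
        if n:
            logger.info("dropping %d strand-ambiguous variants", n)
        return df.loc[~np.asarray(amb)].reset_index(drop=True)

    ref_df = by_id[reference].df
    if drop_ambiguous:
        ref_df = strip_ambiguous(ref_df)
    ref_alleles = {
        (c, p): (a1, a2)
        for c, p, a1, a2 in ref_df[["CHR", "POS", "A1", "A2"]].itertuples(index=False)
    }

    out = []
    for t in tables:
        if t.trait_id == reference:
            out.append(SummaryStatsTable(t.trait_id, ref_df.copy(), t.n_dropped, t.n_flagged_p))
            continue
        df = strip_ambiguous(t.df) if drop_ambiguous else t.df.copy()
        a1 = df["A1"].to_numpy(object)
        a2 = df["A2"].to_numpy(object)
        beta = df["BETA"].to_numpy(float).copy()
        keep = np.ones(len(df), dtype=bool)
        for i, (c, p) in enumerate(zip(df["CHR"].to_numpy(), df["POS"].to_numpy())):
            ref = ref_alleles.get((c, p))
            if ref is None:
                continue
            if (a1[i], a2[i]) == ref:
                continue
            if (a2[i], a1[i]) == ref:
                a1[i], a2[i] = a2[i], a1[i]
                beta[i] = -beta[i]
            else:
                keep[i] = False
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("%s: dropped %d allele-incompatible variants", t.trait_id, n_drop)
        df = df.copy()
        df["A1"], df["A2"], df["BETA"] = a1, a2, beta
        df = df.loc[keep].reset_index(drop=True)
        out.append(SummaryStatsTable(t.trait_id, df, t.n_dropped, t.n_flagged_p))
    return out


def intersect_align(
    tables: Sequence[SummaryStatsTable],
    group_labels: Mapping[str, str] | None = None,
) -> AlignedPanel:
    """Intersect harmonized tables on shared variants into an aligned panel.

    Variant order is the deterministic (CHR, POS, A1, A2) sort; z = beta/se.
    """
    if not tables:
        raise ConfigurationError("no tables to align")
    keysets = [set(map(tuple, t.df[["CHR", "POS", "A1", "A2"]].to_numpy())) for t in tables]
    shared = set.intersection(*keysets)
    if not shared:
        raise InputError("variant intersection across traits is empty")
    variants = pd.DataFrame(sorted(shared), columns=["CHR", "POS", "A1", "A2"])
    idx = pd.MultiIndex.from_frame(variants)
    M, m = len(variants), len(tables)
    Z = np.empty((M, m))
    P = np.empty((M, m))
    N = np.empty(m)
    for j, t in enumerate(tables):
        sub = t.df.set_index(["CHR", "POS", "A1", "A2"]).loc[idx]
        Z[:, j] = sub["BETA"].to_numpy() / sub["SE"].to_numpy()
        P[:, j] = sub["P"].to_numpy()
        N[j] = float(np.median(sub["N"]))
    labels = dict(group_labels or {})
    return AlignedPanel(
        traits=[t.trait_id for t in tables],
        variants=variants,
        Z=Z,
        P=P,
        N=N,
        group_labels=labels,
    )


def exclude_region(panel: AlignedPanel, chrom: int, start: int, end: int) -> AlignedPanel:
    """Drop variants in [start, end] (inclusive, 1-based) on ``chrom``.

    The conventional use is masking the MHC (chr6:25726291-33377699, hg19)
    whose long-range LD distorts both the scan and the mixture model.
    """
    if start >= end:
        raise ConfigurationError("exclusion window requires start < end")
    v = panel.variants
    inside = (v["CHR"] == chrom) & (v["POS"] >= start) & (v["POS"] <= end)
    return panel.subset_variants(~inside.to_numpy())


#: hg19 MHC bounds used throughout as the default exclusion window
MHC_REGION = (6, 25726291, 33377699)
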