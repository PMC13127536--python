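"""LD clumping of significant scan results into independent loci.

Standard post-GWAS locus definition: iterate significant variants by
ascending p-value, keeping a variant as "independent significant" only if it
is in low LD (r^2 < 0.6) with every variant already kept; then merge
independent SNPs within 250 kb of each other (chained) or in r^2 >= 0.1
into genomic loci, each represented by the lead SNP with the lowest scan
p-value. Because any pair with r^2 >= 0.1 lands in one locus, leads of
distinct loci are pairwise r^2 < 0.1 by construction. LD is never defined
across chromosomes and decays to 0 beyond a configurable window (1 Mb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import VariantKey

logger = logging.getLogger("pleioscan")

INDEP_R2 = 0.6
LEAD_R2 = 0.1
MERGE_BP = 250_000
LD_WINDOW_BP = 1_000_000


def ld_from_genotypes(genotypes: np.ndarray, v1: int, v2: int) -> float:
    """Squared Pearson correlation of allele counts between two variants.

    Zero variance at either variant makes r^2 undefined; treated as 0 with a
    warning.
    """
    g1 = np.asarray(genotypes[v1], float)
    g2 = np.asarray(genotypes[v2], float)
    if g1.shape != g2.shape:
        raise ValueError("variant rows differ in length")
    s1, s2 = g1.std(), g2.std()
    if s1 == 0.0 or s2 == 0.0:
        logger.warning("monomorphic variant in r^2 computation; treating r^2 as 0")
        return 0.0
    r = float(np.corrcoef(g1, g2)[0, 1])
    return r * r


class LDSource:
    """Pairwise r^2 lookup, backed by a pair table, a matrix, or genotypes.

    Beyond ``window_bp`` (or across chromosomes) r^2 is defined as 0. A
    lookup miss for a same-window pair is treated as r^2 = 0 with a single
    logged warning.
    """

    def __init__(
        self,
        pairs: dict[tuple[VariantKey, VariantKey], float] | None = None,
        genotypes: np.ndarray | None = None,
        variant_index: dict[VariantKey, int] | None = None,
        window_bp: int = LD_WINDOW_BP,
    ):
        self._pairs = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                if not 0.0 <= r2 <= 1.0:
                    raise ValueError(f"r^2 {r2} outside [0,1]")
                self._pairs[self._key(a, b)] = float(r2)
        self._genotypes = genotypes
        self._index = variant_index or {}
        self.window_bp = window_bp
        self._warned_missing = False

    @staticmethod
    def _key(a: VariantKey, b: VariantKey):
        return (a, b) if a <= b else (b, a)

    @classmethod
    def from_pairs_table(cls, df: pd.DataFrame, window_bp: int = LD_WINDOW_BP) -> "LDSource":
        """3-column table (snp1, snp2, r2) with CHR:POS:A1:A2 identifiers."""

        def parse(s: str) -> VariantKey:
            c, p, a1, a2 = str(s).split(":")
            return VariantKey(int(c), int(p), a1, a2)

        pairs = {
            (parse(r.iloc[0]), parse(r.iloc[1])): float(r.iloc[2])
            for _, r in df.iterrows()
        }
        return cls(pairs=pairs, window_bp=window_bp)

    @classmethod
    def from_matrix(
        cls,
        r2_matrix: np.ndarray,
        variants: list[VariantKey],
        window_bp: int = LD_WINDOW_BP,
    ) -> "LDSource":
        R2 = np.asarray(r2_matrix, float)
        pairs = {}
        nz = np.argwhere(R2 > 0)
        for i, j in nz:
            if i < j:
                pairs[(variants[i], variants[j])] = float(R2[i, j])
        src = cls(pairs=pairs, window_bp=window_bp)
        src._known = set(variants)
        return src

    @classmethod
    def from_genotypes(
        cls,
        genotypes: np.ndarray,
        variants: list[VariantKey],
        window_bp: int = LD_WINDOW_BP,
    ) -> "LDSource":
        return cls(
            genotypes=np.asarray(genotypes),
            variant_index={v: i for i, v in enumerate(variants)},
            window_bp=window_bp,
        )

    def r2(self, a: VariantKey, b: VariantKey) -> float:
        if a == b:
            return 1.0
        if a.chrom != b.chrom or abs(a.pos - b.pos) > self.window_bp:
            return 0.0
        key = self._key(a, b)
        if key in self._pairs:
            return self._pairs[key]
        if self._genotypes is not None and a in self._index and b in self._index:
            return ld_from_genotypes(self._genotypes, self._index[a], self._index[b])
        known = getattr(self, "_known", None)
        if known is not None and a in known and b in known:
            return 0.0  # matrix-backed: absent entry genuinely means 0
        if not self._warned_missing:
            logger.warning("LD lookup miss for same-window pair; assuming r^2=0")
            self._warned_missing = True
        return 0.0


@dataclass
class Locus:
    """A merged genomic locus of independent significant SNPs."""

    locus_id: int
    chrom: int
    start: int
    end: int
    lead: VariantKey
    lead_p: float
    independent_snps: list[VariantKey]
    members: list[VariantKey] = field(default_factory=list)

    @property
    def n_independent(self) -> int:
        return len(self.independent_snps)

    @property
    def n_members(self) -> int:
        return len(self.members)


def _results_keys(results: pd.DataFrame) -> list[VariantKey]:
    return [
        VariantKey(int(c), int(p), a1, a2)
        for c, p, a1, a2 in results[["CHR", "POS", "A1", "A2"]].itertuples(index=False)
    ]


def greedy_independent(
    significant: pd.DataFrame,
    ld: LDSource,
    r2_indep: float = INDEP_R2,
    p_column: str = "p_corrected",
) -> tuple[pd.DataFrame, dict[VariantKey, VariantKey]]:
    """Select independent significant SNPs by greedy ascending-p clumping.

    Iterating by ascending p (ties broken by genomic position for
    determinism), a variant is kept iff its r^2 with every already-kept
    same-chromosome variant within the LD window is below ``r2_indep``.
    Returns the kept rows plus the assignment of each discarded variant to
    the kept variant that tagged it.
    """
    if significant.empty:
        return significant.copy(), {}
    df = significant.sort_values(
        [p_column, "CHR", "POS", "A1", "A2"], kind="stable"
    ).reset_index(drop=True)
    keys = _results_keys(df)
    kept: list[int] = []
    assignment: dict[VariantKey, VariantKey] = {}
    for i, v in enumerate(keys):
        tagger = None
        for ki in kept:
            w = keys[ki]
            if w.chrom == v.chrom and ld.r2(v, w) >= r2_indep:
                tagger = w
                break
        if tagger is None:
            kept.append(i)
        else:
            assignment[v] = tagger
    return df.iloc[kept].reset_index(drop=True), assignment


def merge_loci(
    independent: pd.DataFrame,
    ld: LDSource,
    merge_bp: int = MERGE_BP,
    r2_lead: float = LEAD_R2,
    use_distance: bool = True,
    use_ld: bool = True,
    assignments: dict[VariantKey, VariantKey] | None = None,
    p_column: str = "p_corrected",
) -> list[Locus]:
    """Merge independent significant SNPs into loci and pick lead SNPs.

    Two independent SNPs fall in one locus when they are within ``merge_bp``
    of each other (chained along the chromosome) or in LD r^2 >= ``r2_lead``;
    either rule can be disabled. The lead is the locus member with the lowest
    scan p-value. Tagged (discarded) variants from clumping are carried along
    as locus members.
    """
    if independent.empty:
        return []
    df = independent.sort_values(["CHR", "POS", "A1", "A2"], kind="stable").reset_index(
        drop=True
    )
    keys = _results_keys(df)
    n = len(df)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(n):
        for j in range(i + 1, n):
            if keys[j].chrom != keys[i].chrom:
                break
            close = use_distance and keys[j].pos - keys[i].pos <= merge_bp
            linked = use_ld and ld.r2(keys[i], keys[j]) >= r2_lead
            # distance merging chains through consecutive SNPs only
            if close and j == i + 1 or linked:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    inv_assign: dict[VariantKey, list[VariantKey]] = {}
    for tagged, tagger in (assignments or {}).items():
        inv_assign.setdefault(tagger, []).append(tagged)

    loci = []
    order = sorted(groups.values(), key=lambda g: (keys[g[0]].chrom, keys[g[0]].pos))
    for lid, g in enumerate(order, start=1):
        sub = df.iloc[g]
        ps = sub[p_column].to_numpy()
        lead_row = g[int(np.argmin(ps))]
        members = [keys[i] for i in g]
        tagged_members = [t for i in g for t in inv_assign.get(keys[i], [])]
        loci.append(
            Locus(
                locus_id=lid,
                chrom=keys[g[0]].chrom,
                start=min(k.pos for k in members + tagged_members),
                end=max(k.pos for k in members + tagged_members),
                lead=keys[lead_row],
                lead_p=float(df.iloc[lead_row][p_column]),
                independent_snps=members,
                members=members + tagged_members,
            )
        )
    return loci


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    """Locus summary table: id, lead SNP, span, sizes, lead p."""
    return pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in loci],
            "lead_snp": [str(l.lead) for l in loci],
            "CHR": [l.chrom for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "n_independent": [l.n_independent for l in loci],
            "n_members": [l.n_members for l in loci],
            "lead_p": [l.lead_p for l in loci],
        }
    )
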