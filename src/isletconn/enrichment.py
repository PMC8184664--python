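"""Pre-ranked gene-set enrichment: running-sum ES, permutation null, BH-FDR.

Given a gene list ranked by a differential-expression statistic (e.g. DESeq2
Wald statistics) and a gene set (e.g. a curated epithelial or mesenchymal
EMT list), the enrichment score (ES) is the signed maximum deviation of a
running sum walked down the list: set members ("hits") increment the sum in
proportion to |stat|^weight, non-members ("misses") decrement it by a
constant, so the sum returns to zero at the end of the list.  A high
positive ES means the set clusters at the top of the ranking.

Significance comes from a gene-label permutation null — random same-size
member sets — the only null available for pre-ranked input, with an exact
enumeration mode for small problems.  Families of gene sets are adjusted
with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

#: exact enumeration is used when C(N, n_hits) is at most this
EXACT_ENUMERATION_LIMIT = 20_000


@dataclass(frozen=True)
class RankedGeneList:
    """Genes sorted by statistic, descending; ties broken by gene id."""

    genes: tuple[str, ...]
    stats: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))
        object.__setattr__(
            self, "stats", np.asarray(self.stats, dtype=float)
        )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")
        if self.stats.shape != (len(self.genes),):
            raise ValueError("stats must be 1-D with one value per gene")
        if not np.all(np.isfinite(self.stats)):
            raise ValueError("stats must be finite")
        if np.any(np.diff(self.stats) > 0):
            raise ValueError("stats must be sorted non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_unsorted(cls, genes, stats) -> "RankedGeneList":
        """Sort by statistic descending with a stable gene-id tie-break."""
        df = pd.DataFrame({"gene": [str(g) for g in genes], "stat": np.asarray(stats, float)})
        df = df.sort_values(["stat", "gene"], ascending=[False, True], kind="mergesort")
        return cls(tuple(df["gene"]), df["stat"].to_numpy())

    @classmethod
    def read_rnk(cls, path) -> "RankedGeneList":
        """Read a two-column RNK file (gene, statistic; tab- or whitespace-separated)."""
        df = pd.read_csv(path, sep=r"\s+", header=None, names=["gene", "stat"], comment="#")
        return cls.from_unsorted(df["gene"].astype(str), df["stat"].astype(float))

    def write_rnk(self, path) -> None:
        pd.DataFrame({"gene": self.genes, "stat": self.stats}).to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(str(m) for m in self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members per line)."""
    sets = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{ln}: GMT line needs name, description and >=1 member"
                )
            sets.append(GeneSet(fields[0], frozenset(fields[2:]), fields[1]))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


@dataclass
class EnrichmentResult:
    """ES with permutation significance for one (ranked list, gene set) pair."""

    set_name: str
    set_size: int  # members present in the ranked list
    es: float
    nes: float
    p_perm: float
    n_perm: int
    seed: int | None
    leading_edge: tuple[str, ...]
    exact: bool = False
    q_bh: float | None = None
    n_null_same_sign: int | None = None


def _hit_mask(ranked: RankedGeneList, gs: GeneSet) -> np.ndarray:
    mask = np.fromiter((g in gs.members for g in ranked.genes), bool, len(ranked))
    absent = len(gs.members) - int(mask.sum())
    if absent:
        log.info(
            "gene set %s: %d member(s) absent from the ranked list (dropped)",
            gs.name,
            absent,
        )
    return mask


def _es_from_mask(stats: np.ndarray, mask: np.ndarray, weight: float) -> tuple[float, np.ndarray]:
    """Running-sum ES for a hit mask; returns (es, running profile)."""
    n = stats.size
    n_hit = int(mask.sum())
    w = np.abs(stats) ** weight if weight != 0 else np.ones(n)
    denom = float(w[mask].sum())
    if denom <= 0:
        raise ValueError("all hit weights are zero; use weight=0 or rescale stats")
    steps = np.where(mask, w / denom, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    i_max = int(np.argmax(np.abs(running)))
    return float(running[i_max]), running


def enrichment_score(
    ranked: RankedGeneList, gs: GeneSet, weight: float = 1.0
) -> tuple[float, np.ndarray, tuple[str, ...]]:
    """Signed maximum deviation of the running sum, with its profile and
    leading edge.

    Hits increment the sum by ``|stat|^weight / Σ_set |stat|^weight``; misses
    decrement it by ``1 / (N − N_hit)``.  The leading edge holds the members
    at or before the extremum (at or after it for a negative ES).
    """
    mask = _hit_mask(ranked, gs)
    n_hit = int(mask.sum())
    if n_hit == 0:
        raise ValueError(f"gene set {gs.name!r} has no overlap with the ranked list")
    if n_hit == len(ranked):
        raise ValueError(
            f"gene set {gs.name!r} covers the whole ranked list; miss step undefined"
        )
    es, running = _es_from_mask(ranked.stats, mask, weight)
    i_max = int(np.argmax(np.abs(running)))
    if es >= 0:
        lead = [g for k, g in enumerate(ranked.genes) if mask[k] and k <= i_max]
    else:
        lead = [g for k, g in enumerate(ranked.genes) if mask[k] and k >= i_max]
    return es, running, tuple(lead)


def _null_es(
    stats: np.ndarray,
    n: int,
    n_hit: int,
    weight: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    out = np.empty(n_perm)
    for k in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n_hit, replace=False)] = True
        out[k], _ = _es_from_mask(stats, mask, weight)
    return out


def _exact_null_es(stats: np.ndarray, n: int, n_hit: int, weight: float) -> np.ndarray:
    out = np.empty(math.comb(n, n_hit))
    mask = np.zeros(n, dtype=bool)
    for k, combo in enumerate(itertools.combinations(range(n), n_hit)):
        mask[:] = False
        mask[list(combo)] = True
        out[k], _ = _es_from_mask(stats, mask, weight)
    return out


def permutation_significance(
    ranked: RankedGeneList,
    gs: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    exact: bool | None = None,
) -> EnrichmentResult:
    """ES with a gene-label permutation p-value and sign-matched NES.

    The null draws ``n_perm`` random member sets of the same size (without
    replacement) from the ranked list.  The p-value is sign-stratified, as
    is standard for the signed ES: only null scores with the sign of the
    observed ES enter, ``p = (1 + #{same-sign null at least as extreme}) /
    (n_same_sign + 1)``, which is approximately uniform under the null.
    The NES is the ES divided by the mean |null ES| of the same sign.  When
    ``exact`` is true (or unset and C(N, n_hit) <= 20,000) every placement
    is enumerated instead and the p-value is the exact same-sign fraction
    at least as extreme (the observed placement is among them, so p > 0).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    es, _, lead = enrichment_score(ranked, gs, weight)
    mask = _hit_mask(ranked, gs)
    n, n_hit = len(ranked), int(mask.sum())
    n_placements = math.comb(n, n_hit)
    if exact is None:
        exact = n_placements <= EXACT_ENUMERATION_LIMIT
    if exact:
        if n_placements > EXACT_ENUMERATION_LIMIT:
            raise ValueError(
                f"exact enumeration infeasible: C({n},{n_hit}) = {n_placements} "
                f"> {EXACT_ENUMERATION_LIMIT}"
            )
        null = _exact_null_es(ranked.stats, n, n_hit, weight)
        same_sign = null >= 0 if es >= 0 else null <= 0
        n_same = int(same_sign.sum())  # >= 1: the observed placement is included
        if es >= 0:
            extreme = int(np.count_nonzero(null[same_sign] >= es))
        else:
            extreme = int(np.count_nonzero(null[same_sign] <= es))
        p = extreme / n_same
        n_used = null.size
        n_same_sign = n_same
    else:
        null = _null_es(ranked.stats, n, n_hit, weight, n_perm, np.random.default_rng(seed))
        same_sign = null >= 0 if es >= 0 else null <= 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            raise ValueError(
                "no same-sign null scores; increase n_perm to estimate this p-value"
            )
        if es >= 0:
            extreme = int(np.count_nonzero(null[same_sign] >= es))
        else:
            extreme = int(np.count_nonzero(null[same_sign] <= es))
        p = (1 + extreme) / (n_same + 1)
        n_used = n_perm
        n_same_sign = n_same
    same_sign_null = null[null >= 0] if es >= 0 else null[null <= 0]
    mean_abs = float(np.abs(same_sign_null).mean()) if same_sign_null.size else np.nan
    nes = es / mean_abs if mean_abs and np.isfinite(mean_abs) and mean_abs > 0 else np.nan
    return EnrichmentResult(
        set_name=gs.name,
        set_size=n_hit,
        es=es,
        nes=nes,
        p_perm=p,
        n_perm=n_used,
        seed=None if exact else seed,
        leading_edge=lead,
        exact=bool(exact),
        n_null_same_sign=n_same_sign,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    Values must lie in (0, 1]; output is elementwise >= input and monotone
    non-decreasing when sorted by raw p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def score_gene_sets(
    ranked: RankedGeneList,
    gene_sets,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    exact: bool | None = None,
) -> pd.DataFrame:
    """Score a family of gene sets and BH-adjust the permutation p-values.

    Returns a table ``set, size, es, nes, p, q, leading_edge`` in the input
    set order.  Each set gets its own deterministic RNG substream.
    """
    results = []
    for k, gs in enumerate(gene_sets):
        sub_seed = np.random.SeedSequence(seed, spawn_key=(k,))
        res = permutation_significance(
            ranked, gs, n_perm=n_perm,
            seed=int(sub_seed.generate_state(1)[0] % (2**31)),
            weight=weight, exact=exact,
        )
        results.append(res)
    q = bh_adjust([r.p_perm for r in results])
    for r, qv in zip(results, q):
        r.q_bh = float(qv)
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "size": [r.set_size for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p_perm for r in results],
            "q": [r.q_bh for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    )
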