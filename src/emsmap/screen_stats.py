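"""Gene-level enrichment of screen mutations against the probability map.

Under the map's null model every base of every strain mutates independently
with probability ``P_i`` (a Bernoulli trial), so the expected number of
events in a sequence across a pool of ``n`` strains is

    E(seq) = n * sum_{i in seq} P_i

and the observed count follows a Poisson-binomial distribution, well
approximated by Poisson(E) for the tiny per-base probabilities involved.
Batch-to-batch differences in mutagen strength are absorbed by the
effectiveness scalar ``alpha_1 = (mean events/strain in the batch) /
(mean events/strain in the baseline cohort)``.

Two-sided p-values default to the exact probability-mass ("minlike") method
with a mid-p correction, which keeps the discrete test close to its nominal
size for the small expected counts typical of single genes; the classical
doubled-tail p-value and one-sided enrichment tests are available through
``tail`` / ``alternative``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import IMPACT_CLASSES, GeneModel, MutationDataset
from .rf_model import MutProbMap

logger = logging.getLogger(__name__)

#: impact/variant classes treated as plausibly function-disrupting
HIGH_IMPACT_CLASSES = ("stop_gain", "splicing", "missense")


@dataclass(frozen=True)
class BatchEffectiveness:
    """Mutagen-effectiveness scaling between two cohorts."""

    n_bar_0: float  # mean events per strain, baseline cohort
    n_bar_1: float  # mean events per strain, analysed batch
    alpha_0: float = 1.0
    alpha_1: float = float("nan")


def batch_effectiveness(
    baseline: MutationDataset, batch: MutationDataset, alpha_0: float = 1.0
) -> BatchEffectiveness:
    """alpha_1 = (N_bar_1 / N_bar_0) * alpha_0 from per-strain event means."""
    if len(baseline) == 0:
        raise ValueError("baseline cohort has no mutation events")
    if len(batch) == 0:
        raise ValueError("analysed batch has no mutation events")
    n0 = baseline.events_per_strain()
    n1 = batch.events_per_strain()
    return BatchEffectiveness(n0, n1, alpha_0, n1 / n0 * alpha_0)


# ---------------------------------------------------------------------------
# expectations
# ---------------------------------------------------------------------------


def seq_probability(map: MutProbMap, chrom: str, start: int, end: int) -> float:
    """P_seq = sum of per-base P over [start, end) (0-based half-open)."""
    if chrom not in map.values:
        raise ValueError(f"chromosome {chrom!r} not in map")
    v = map.values[chrom]
    if start < 0 or end > len(v):
        raise ValueError(f"interval {chrom}:{start}-{end} outside map")
    if end <= start:
        return 0.0
    return float(v[start:end].sum())


def gene_probability(map: MutProbMap, gene: GeneModel) -> float:
    """P_seq over the union of a gene's intervals."""
    return sum(seq_probability(map, gene.chrom, s, e) for s, e in gene.intervals)


def expected_count(
    map: MutProbMap, interval: GeneModel | tuple[str, int, int], n_strains: int
) -> float:
    """E(seq) = n_strains * P_seq for a gene or a (chrom, start, end) interval."""
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if isinstance(interval, GeneModel):
        p = gene_probability(map, interval)
    else:
        p = seq_probability(map, *interval)
    return n_strains * p


# ---------------------------------------------------------------------------
# null distributions and p-values
# ---------------------------------------------------------------------------


def poisson_binomial_pmf(
    per_base_p: np.ndarray, n_strains: int, tail_tol: float = 1e-12
) -> np.ndarray:
    """Exact pmf of the event count over ``n_strains`` independent Bernoulli
    trials per base, by convolving per-base Binomial(n, p) pmfs.

    Feasible for small genes; the support is truncated where the remaining
    mass drops below ``tail_tol``.
    """
    per_base_p = np.asarray(per_base_p, dtype=float)
    # spread the permissible truncation error over all convolution steps so
    # the accumulated loss stays below tail_tol even for kilobase genes
    step_tol = tail_tol / max(1, 2 * len(per_base_p))
    pmf = np.array([1.0])
    for p in per_base_p:
        if p == 0:
            continue
        base = stats.binom.pmf(np.arange(n_strains + 1), n_strains, p)
        nz = np.flatnonzero(base > step_tol)
        base = base[: (nz[-1] + 1) if len(nz) else 1]
        pmf = np.convolve(pmf, base)
        # drop a vanishing upper tail to keep the support small
        csum = np.cumsum(pmf[::-1])[::-1]
        cut = np.flatnonzero(csum > step_tol)
        pmf = pmf[: cut[-1] + 1] if len(cut) else pmf[:1]
    return pmf / pmf.sum()


def _pvalue_from_pmf(pmf: np.ndarray, x: int, tail: str, alternative: str) -> float:
    """p-value of observing ``x`` under a discrete null pmf on 0..len-1."""
    k = np.arange(len(pmf))
    if x >= len(pmf):  # beyond the stored support: essentially zero upper tail
        pmf_x = 0.0
        upper = 0.0
        lower = 1.0
    else:
        pmf_x = pmf[x]
        upper = pmf[k >= x].sum()
        lower = pmf[k <= x].sum()
    if alternative == "greater":
        if tail == "midp":
            return float(max(min(upper - 0.5 * pmf_x, 1.0), 0.0))
        return float(min(upper, 1.0))
    if alternative != "two-sided":
        raise ValueError(f"unknown alternative {alternative!r}")
    if tail == "doubling":
        return float(min(1.0, 2.0 * min(lower, upper)))
    if tail == "midp":
        # probability-mass (minlike) two-sided p with mid-p correction
        lt = pmf[pmf < pmf_x * (1 - 1e-12)].sum() if pmf_x > 0 else pmf.sum()
        eq = pmf[np.abs(pmf - pmf_x) <= pmf_x * 1e-12].sum() if pmf_x > 0 else 0.0
        return float(max(min(lt + 0.5 * eq, 1.0), 0.0))
    if tail == "minlike":
        if pmf_x == 0:
            return 0.0
        return float(min(pmf[pmf <= pmf_x * (1 + 1e-12)].sum(), 1.0))
    raise ValueError(f"unknown tail {tail!r}")


def poisson_pmf_support(mean: float, x: int) -> np.ndarray:
    """Poisson pmf over a support wide enough for p-value computation."""
    hi = int(max(x + 1, np.ceil(mean + 10 * np.sqrt(mean) + 20)))
    return stats.poisson.pmf(np.arange(hi + 1), mean)


def count_pvalue(
    observed: int,
    expected: float,
    per_base_p: np.ndarray | None = None,
    n_strains: int | None = None,
    method: str = "poisson",
    tail: str = "midp",
    alternative: str = "two-sided",
    conditional: bool = False,
) -> float:
    """p-value of an observed event count under the map's null model.

    ``method="poisson"`` uses the Poisson(expected) limit; ``"exact"``
    convolves the per-base Binomial pmfs (requires ``per_base_p`` and
    ``n_strains``, practical for small genes only).  With ``conditional``
    the null is zero-truncated (counts conditioned on being positive) —
    the correct reference when only genes carrying at least one mutation
    are ever tested.
    """
    if expected <= 0:
        raise ValueError("expected count must be positive for tested genes")
    if method == "poisson":
        pmf = poisson_pmf_support(expected, observed)
    elif method == "exact":
        if per_base_p is None or n_strains is None:
            raise ValueError("exact method needs per_base_p and n_strains")
        pmf = poisson_binomial_pmf(per_base_p, n_strains)
    else:
        raise ValueError(f"unknown method {method!r}")
    if conditional:
        if observed < 1:
            raise ValueError("conditional p-value requires observed >= 1")
        pmf = pmf.copy()
        pmf[0] = 0.0
        pmf /= pmf.sum()
    return _pvalue_from_pmf(pmf, observed, tail, alternative)


# ---------------------------------------------------------------------------
# background removal
# ---------------------------------------------------------------------------


def remove_background(
    pool: MutationDataset, share_frac: float = 0.25
) -> MutationDataset:
    """Remove variants shared by at least ``share_frac`` of the pool's strains.

    A variant is identified by (chrom, pos, alt); all copies of a shared
    variant are removed from every strain.  Such widely shared variants are
    pre-existing or clonal background, not independent EMS events.
    """
    if pool.n_strains < 2:
        raise ValueError("background removal needs a pool of at least 2 strains")
    df = pool.df
    shared = (
        df.drop_duplicates(["strain", "chrom", "pos", "alt"])
        .groupby(["chrom", "pos", "alt"])
        .size()
    )
    cutoff = share_frac * pool.n_strains
    background = shared[shared >= cutoff]
    if len(background):
        logger.info(
            "removing %d background variants shared by >= %.0f%% of %d strains",
            len(background), share_frac * 100, pool.n_strains,
        )
    key = pd.MultiIndex.from_frame(df[["chrom", "pos", "alt"]])
    keep = ~key.isin(background.index)
    return MutationDataset(
        df[keep], batch_label=pool.batch_label, n_strains=pool.n_strains
    )


# ---------------------------------------------------------------------------
# enrichment testing
# ---------------------------------------------------------------------------


def gene_enrichment(
    pool: MutationDataset,
    genes: dict[str, GeneModel],
    map: MutProbMap,
    alpha_1: float = 1.0,
    fdr: float = 0.05,
    method: str = "poisson",
    tail: str = "midp",
    alternative: str = "two-sided",
    conditional: bool = True,
    exact_max_length: int = 2000,
) -> pd.DataFrame:
    """Per-gene observed vs expected mutation counts in a screen pool.

    For every gene with at least one observed event: the expected count is
    ``alpha_1 * n_pool * sum P_i`` over the gene territory, the p-value
    tests the observed count against the map's null counting model
    (zero-truncated by default, matching the restriction to mutated genes),
    and q-values are Benjamini-Hochberg over the tested genes.  With
    ``method="auto"`` genes up to ``exact_max_length`` bases use the exact
    Poisson-binomial null and longer genes the Poisson limit.

    Returns a DataFrame sorted by q-value with columns gene_id, chrom,
    length, observed, expected, fold_change, p_value, q_value, high_impact,
    one count column per impact class, and ``significant`` at the given FDR.
    """
    if not genes:
        raise ValueError("no genes supplied")
    n_pool = pool.n_strains
    pos_by_chrom = {
        c: np.sort(sub["pos"].to_numpy(dtype=np.int64))
        for c, sub in pool.df.groupby("chrom")
    }

    rows = []
    for gene in genes.values():
        if gene.chrom not in map.values:
            raise ValueError(f"gene {gene.gene_id} on chromosome absent from map")
        v = map.values[gene.chrom]
        if gene.span[1] > len(v):
            raise ValueError(f"gene {gene.gene_id} extends beyond the map")
        p_seq = float(sum(v[s:e].sum() for s, e in gene.intervals))
        positions = pos_by_chrom.get(gene.chrom, np.empty(0, dtype=np.int64))
        observed = int(
            sum(
                np.searchsorted(positions, e) - np.searchsorted(positions, s)
                for s, e in gene.intervals
            )
        )
        if observed == 0:
            continue
        expected = alpha_1 * n_pool * p_seq
        gmethod = method
        if method == "auto":
            gmethod = "exact" if gene.length <= exact_max_length else "poisson"
        per_base = None
        if gmethod == "exact":
            per_base = alpha_1 * np.concatenate(
                [map.values[gene.chrom][s:e] for s, e in gene.intervals]
            )
        p = count_pvalue(
            observed, expected, per_base, n_pool, gmethod, tail, alternative,
            conditional=conditional,
        )
        prof = impact_profile(pool, gene)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "chrom": gene.chrom,
                "length": gene.length,
                "observed": observed,
                "expected": expected,
                "fold_change": observed / expected,
                "p_value": p,
                "high_impact": prof.high_impact,
                **{f"n_{c}": prof.counts.get(c, 0) for c in IMPACT_CLASSES},
                "n_indel": prof.counts.get("InDel", 0),
            }
        )
    if not rows:
        raise ValueError("no gene in the annotation carries observed mutations")
    out = pd.DataFrame(rows)
    _, qvals, _, _ = multipletests(out["p_value"], method="fdr_bh")
    out["q_value"] = qvals
    out["significant"] = out["q_value"] < fdr
    return out.sort_values(["q_value", "p_value"]).reset_index(drop=True)


@dataclass
class ImpactProfile:
    """Impact-class breakdown of a gene's mutations in a pool."""

    gene_id: str
    counts: dict[str, int]  # per impact class; InDels under key "InDel"
    high_impact: int
    per_strain_high_impact: dict[str, int]


def impact_profile(pool: MutationDataset, gene: GeneModel) -> ImpactProfile:
    """Count a gene's pool mutations per impact class.

    High-impact events are InDels plus stop-gain, splicing and missense
    SNVs.  Unknown annotation strings are counted as "other" with a logged
    warning; the per-strain table supports checks that each selected strain
    carries a high-impact hit.
    """
    df = pool.df[pool.df["chrom"] == gene.chrom]
    if len(df):
        in_gene = np.zeros(len(df), dtype=bool)
        pos = df["pos"].to_numpy(dtype=np.int64)
        for s, e in gene.intervals:
            in_gene |= (pos >= s) & (pos < e)
        df = df[in_gene]
    counts: dict[str, int] = {}
    per_strain: dict[str, int] = {}
    high = 0
    for row in df.itertuples(index=False):
        if row.variant_class == "InDel":
            cls = "InDel"
        else:
            cls = row.impact if not pd.isna(row.impact) else "other"
            if cls not in IMPACT_CLASSES:
                logger.warning("unknown impact annotation %r -> 'other'", cls)
                cls = "other"
        counts[cls] = counts.get(cls, 0) + 1
        if cls == "InDel" or cls in HIGH_IMPACT_CLASSES:
            high += 1
            per_strain[row.strain] = per_strain.get(row.strain, 0) + 1
    return ImpactProfile(gene.gene_id, counts, high, per_strain)
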