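"""Model-fit metrics and feature attribution.

R-squared is the plain ``1 - MSE/Var`` form with the population variance.
Block validation compares expected (n * sum P) and observed mutation counts
over genomic blocks, formed either positionally from each chromosome start
or after sorting bases by their predicted rate.  Permutation importance of
feature j is the drop in R-squared when column j is replaced by a
distribution-preserving shuffle of itself, averaged over n shuffles, with
min-max normalisation across features for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MutationDataset, ReferenceGenome
from .rf_model import MutProbMap


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination, 1 - MSE / Var(y) (population variance)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("y and yhat must be equal-length non-empty arrays")
    var = np.mean((y - y.mean()) ** 2)
    if var == 0:
        raise ValueError("Var(y) is zero; R^2 undefined")
    mse = np.mean((y - yhat) ** 2)
    return float(1.0 - mse / var)


def minmax_normalize(v: np.ndarray) -> np.ndarray:
    """V = (v - min) / (max - min); NaN when all values are equal."""
    v = np.asarray(v, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.full_like(v, np.nan)
    return (v - lo) / (hi - lo)


@dataclass
class BlockValidation:
    """Expected vs observed mutation counts per genomic block."""

    table: pd.DataFrame  # columns: block, expected, observed (+chrom/start in positional mode)
    pearson_r: float  # NaN when degenerate
    degenerate: bool
    block_size: int
    mode: str  # "positional" or "sorted"


def block_validation(
    map: MutProbMap,
    dataset: MutationDataset,
    block_size: int = 100_000,
    sort_by_prediction: bool = False,
) -> BlockValidation:
    """Compare expected and observed counts over blocks of ``block_size`` bases.

    Positional mode tiles every chromosome from its first base; sorted mode
    orders all bases by predicted rate and cuts consecutive groups of
    ``block_size`` bases, so blocks span the prediction range.  Expected is
    ``n_strains * sum P`` per block; Pearson r is computed over blocks and
    flagged degenerate when either side is constant.
    """
    n = dataset.n_strains
    events = {
        c: np.bincount(
            sub["pos"].to_numpy(dtype=np.int64), minlength=len(map.values[c])
        )
        for c, sub in dataset.df.groupby("chrom")
    }
    rows = []
    if sort_by_prediction:
        p_all = np.concatenate([map.values[c] for c in map.values])
        e_all = np.concatenate(
            [
                events.get(c, np.zeros(len(map.values[c]), dtype=np.int64))
                for c in map.values
            ]
        )
        order = np.argsort(p_all, kind="stable")
        p_all, e_all = p_all[order], e_all[order]
        for b, start in enumerate(range(0, len(p_all), block_size)):
            sl = slice(start, start + block_size)
            rows.append(
                {"block": b, "expected": n * p_all[sl].sum(), "observed": int(e_all[sl].sum())}
            )
        mode = "sorted"
    else:
        b = 0
        for chrom, v in map.values.items():
            ev = events.get(chrom, np.zeros(len(v), dtype=np.int64))
            for start in range(0, len(v), block_size):
                sl = slice(start, start + block_size)
                rows.append(
                    {
                        "block": b,
                        "chrom": chrom,
                        "start": start,
                        "expected": n * v[sl].sum(),
                        "observed": int(ev[sl].sum()),
                    }
                )
                b += 1
        mode = "positional"
    table = pd.DataFrame(rows)
    exp, obs = table["expected"].to_numpy(), table["observed"].to_numpy(float)
    degenerate = len(table) < 2 or np.ptp(exp) == 0 or np.ptp(obs) == 0
    r = float("nan") if degenerate else float(stats.pearsonr(exp, obs)[0])
    return BlockValidation(table, r, degenerate, block_size, mode)


def gc_correlation(
    genome: ReferenceGenome, dataset: MutationDataset, window: int = 100_000
) -> dict[str, float]:
    """Per-chromosome Pearson r between G/C content and mutation counts.

    Windows are tiled from the first base of each chromosome; a trailing
    partial window is kept.  Chromosomes shorter than one window are
    skipped; constant G/C across windows gives NaN.
    """
    out: dict[str, float] = {}
    for chrom, seq in genome.chromosomes.items():
        if len(seq) < window:
            continue
        enc = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_gc = (enc == ord("G")) | (enc == ord("C"))
        sub = dataset.df[dataset.df["chrom"] == chrom]
        ev = np.bincount(sub["pos"].to_numpy(dtype=np.int64), minlength=len(seq))
        edges = list(range(0, len(seq), window)) + [len(seq)]
        gc = np.array([is_gc[s:e].sum() for s, e in zip(edges, edges[1:])], dtype=float)
        mu = np.array([ev[s:e].sum() for s, e in zip(edges, edges[1:])], dtype=float)
        if np.ptp(gc) == 0 or np.ptp(mu) == 0:
            out[chrom] = float("nan")
        else:
            out[chrom] = float(stats.pearsonr(gc, mu)[0])
    return out


def permutation_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    n_shuffles: int = 10,
    seed: int = 0,
    column_names: list[str] | None = None,
    parametric_noise: bool = False,
) -> pd.DataFrame:
    """Permutation importance i_j = R^2 - (1/n) sum_i R^2_{i,j}.

    Each feature column is replaced n times by a permutation of its own
    values (exactly preserving the marginal distribution) and the model's
    R-squared recomputed; ``parametric_noise`` instead resamples the column
    i.i.d. from its empirical distribution.  The normalised column ``V``
    min-max scales the raw importances to [0, 1]; with a single feature V
    is NaN.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    X = np.asarray(X)
    rng = np.random.default_rng(seed)
    base_r2 = r_squared(y, model.predict(X))
    raw = []
    for j in range(X.shape[1]):
        scores = []
        for _ in range(n_shuffles):
            Xp = X.copy()
            if parametric_noise:
                Xp[:, j] = rng.choice(X[:, j], size=X.shape[0], replace=True)
            else:
                Xp[:, j] = rng.permutation(X[:, j])
            scores.append(r_squared(y, model.predict(Xp)))
        raw.append(base_r2 - float(np.mean(scores)))
    raw = np.asarray(raw)
    if column_names is None:
        column_names = getattr(model, "column_order", None) or [
            f"feature_{j}" for j in range(X.shape[1])
        ]
    return pd.DataFrame(
        {
            "feature": list(column_names),
            "importance": raw,
            "V": minmax_normalize(raw),
            "r2_model": base_r2,
            "n_shuffles": n_shuffles,
        }
    )
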