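"""Smoothing of DNA-binding-protein tracks and per-base feature assembly.

Raw ChIP signal is smoothed with a centred 100-bp moving average per
chromosome before entering the model.  The feature matrix has one row per
retained genomic base (bases with a complete, N-free 5-mer window) and one
column per smoothed protein track plus the sequence-context baseline P0.
The regression target is y = (mutation events at the base across the
training cohort) / n_strains, i.e. the per-strain per-base event
probability, so the forest output is directly a per-strain probability and
the training cohort's mutagen effectiveness is 1 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .context_model import BaselineTrack
from .io_formats import MutationDataset, ReferenceGenome, SignalTrack


def sliding_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; the window shrinks at the array edges.

    For even ``window`` the extra element sits on the right.  A window not
    smaller than the array yields the global mean everywhere.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return values.copy()
    if window >= n:
        return np.full(n, values.mean())
    half_left = (window - 1) // 2
    half_right = window - half_left  # exclusive right offset
    csum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    left = np.clip(idx - half_left, 0, n)
    right = np.clip(idx + half_right, 0, n)
    return (csum[right] - csum[left]) / (right - left)


def smooth_track(track: SignalTrack, window: int = 100) -> SignalTrack:
    """Smooth every chromosome of a track with a centred moving average."""
    out = {c: sliding_mean(v, window) for c, v in track.values.items()}
    return SignalTrack(track.feature_name, out, smoothed=True, window=window)


@dataclass
class FeatureMatrix:
    """Per-base design matrix for the mutation-probability regressor.

    ``X`` holds one row per retained base in genome order; ``column_order``
    names the columns (protein features then ``"P0"``).  ``baseline`` keeps
    the full-genome per-strain baseline used to fill bases excluded from the
    matrix (chromosome edges, N windows) at prediction time.
    """

    X: np.ndarray  # (n_rows, n_features) float32
    y: np.ndarray  # (n_rows,) per-strain per-base event probability
    column_order: list[str]
    chrom_names: list[str]
    row_chrom: np.ndarray  # (n_rows,) int32 index into chrom_names
    row_pos: np.ndarray  # (n_rows,) int64 0-based position
    n_strains: int  # training cohort size behind y
    chrom_sizes: dict[str, int]
    baseline: dict[str, np.ndarray]  # per-strain baseline per base (full genome)
    flags: dict[str, np.ndarray]  # True where the base was excluded

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def take(self, rows: np.ndarray) -> "FeatureMatrix":
        """Row subset (same metadata); used for train/test splits."""
        return FeatureMatrix(
            self.X[rows],
            self.y[rows],
            self.column_order,
            self.chrom_names,
            self.row_chrom[rows],
            self.row_pos[rows],
            self.n_strains,
            self.chrom_sizes,
            self.baseline,
            self.flags,
        )


def build_features(
    genome: ReferenceGenome,
    tracks: list[SignalTrack],
    p0track: BaselineTrack,
    training: MutationDataset,
) -> FeatureMatrix:
    """Assemble the per-base feature matrix.

    One row per base whose 5-mer context is complete (not flagged in
    ``p0track``); columns are the smoothed tracks in input order followed by
    the P0 baseline.  Every track must be smoothed and cover every
    chromosome of the genome.
    """
    for t in tracks:
        if not t.smoothed:
            raise ValueError(f"track {t.feature_name!r} is not smoothed")
        missing = set(genome.chromosomes) - set(t.values)
        if missing:
            raise ValueError(
                f"track {t.feature_name!r} missing chromosomes {sorted(missing)}"
            )
    sizes = genome.chrom_sizes()
    chrom_names = list(genome.chromosomes)
    n_strains = training.n_strains

    events: dict[str, np.ndarray] = {
        c: np.zeros(sizes[c], dtype=np.int64) for c in chrom_names
    }
    for chrom, sub in training.df.groupby("chrom"):
        if chrom not in events:
            raise ValueError(f"training record on unknown chromosome {chrom!r}")
        pos = sub["pos"].to_numpy(dtype=np.int64)
        events[chrom] += np.bincount(pos, minlength=sizes[chrom])

    blocks_X, blocks_y, blocks_c, blocks_p = [], [], [], []
    baseline: dict[str, np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}
    for ci, chrom in enumerate(chrom_names):
        flag = p0track.flags[chrom]
        keep = ~flag
        cols = [t.values[chrom][keep] for t in tracks]
        cols.append(p0track.values[chrom][keep])
        blocks_X.append(np.column_stack(cols).astype(np.float32))
        blocks_y.append(events[chrom][keep] / n_strains)
        pos = np.flatnonzero(keep)
        blocks_p.append(pos)
        blocks_c.append(np.full(len(pos), ci, dtype=np.int32))
        baseline[chrom] = p0track.values[chrom] / n_strains
        flags[chrom] = flag.copy()

    column_order = [t.feature_name for t in tracks] + ["P0"]
    return FeatureMatrix(
        X=np.concatenate(blocks_X),
        y=np.concatenate(blocks_y),
        column_order=column_order,
        chrom_names=chrom_names,
        row_chrom=np.concatenate(blocks_c),
        row_pos=np.concatenate(blocks_p),
        n_strains=n_strains,
        chrom_sizes=sizes,
        baseline=baseline,
        flags=flags,
    )
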