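"""Flanking-sequence baseline mutation probability (P0) per 5-mer.

EMS mutagenesis is biased by the local sequence context: some 5-base
patterns mutate an order of magnitude more often than others.  The baseline
probability of a pattern is

    P0 = C' / C0

where ``C'`` counts mutation events in a training catalogue whose mutated
base sits at the centre of the pattern and ``C0`` counts occurrences of the
pattern in the reference genome.  P0 is therefore events per pattern
occurrence *over the whole training cohort*; the per-strain probability is
obtained downstream by dividing by the cohort's strain count.

5-mers are taken on the reference forward strand and complementary patterns
are kept as separate rows, so all four central bases are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MutationDataset, ReferenceGenome

K = 5
FLANK = K // 2
N_PATTERNS = 4**K

_BASES = "ACGT"
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8: A,C,G,T -> 0..3, anything else 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def pattern_to_code(pattern: str) -> int:
    code = 0
    for b in pattern:
        i = _BASES.find(b)
        if i < 0:
            raise ValueError(f"pattern {pattern!r} contains non-ACGT base")
        code = code * 4 + i
    return code


def code_to_pattern(code: int) -> str:
    out = []
    for _ in range(K):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def _kmer_codes(enc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-center codes and validity for all centres 0..L-1 of one chromosome.

    The code at centre ``i`` covers bases ``i-2..i+2``; centres whose window
    leaves the chromosome or contains a non-ACGT base are invalid.
    """
    L = len(enc)
    codes = np.full(L, -1, dtype=np.int64)
    valid = np.zeros(L, dtype=bool)
    if L < K:
        return codes, valid
    w = enc.astype(np.int64)
    c = ((((w[:-4] * 4 + w[1:-3]) * 4 + w[2:-2]) * 4 + w[3:-1]) * 4) + w[4:]
    ok = (
        (w[:-4] < 4) & (w[1:-3] < 4) & (w[2:-2] < 4) & (w[3:-1] < 4) & (w[4:] < 4)
    )
    codes[FLANK : L - FLANK] = np.where(ok, c, -1)
    valid[FLANK : L - FLANK] = ok
    return codes, valid


@dataclass
class ContextTable:
    """Per-5-mer genome counts, mutation-event counts and P0 = C'/C0."""

    c0: np.ndarray  # (1024,) pattern occurrences in the genome
    c_prime: np.ndarray  # (1024,) mutation events centred on the pattern
    n_strains: int  # strains in the training cohort
    skipped_events: int = 0  # InDels and edge/N-window SNVs not counted

    def __post_init__(self) -> None:
        self.c0 = np.asarray(self.c0, dtype=np.int64)
        self.c_prime = np.asarray(self.c_prime, dtype=np.int64)
        bad = (self.c0 == 0) & (self.c_prime > 0)
        if bad.any():
            pats = [code_to_pattern(i) for i in np.flatnonzero(bad)[:5]]
            raise ValueError(
                f"catalogue inconsistent with genome: events on absent patterns {pats}"
            )

    @property
    def p0(self) -> np.ndarray:
        """P0 per pattern code; NaN where the pattern is unobserved (C0 = 0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.c_prime / np.where(self.c0 > 0, self.c0, 0)
        out[self.c0 == 0] = np.nan
        return out

    def p0_of(self, pattern: str) -> float:
        return float(self.p0[pattern_to_code(pattern)])

    def central_base_marginal(self) -> np.ndarray:
        """Mean event frequency per central base b: sum C' / sum C0 over
        patterns centred on b.  The fallback for edge/N/unobserved bases."""
        centers = (np.arange(N_PATTERNS) // 4**FLANK) % 4
        marg = np.zeros(4)
        for b in range(4):
            m = centers == b
            tot = self.c0[m].sum()
            marg[b] = self.c_prime[m].sum() / tot if tot > 0 else 0.0
        return marg

    def to_frame(self) -> pd.DataFrame:
        """Table with columns pattern, C0, C_prime, P0 (one row per 5-mer)."""
        patterns = [code_to_pattern(i) for i in range(N_PATTERNS)]
        return pd.DataFrame(
            {"pattern": patterns, "C0": self.c0, "C_prime": self.c_prime, "P0": self.p0}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class BaselineTrack:
    """Per-base P0 with a flag for bases filled by the central-base marginal."""

    values: dict[str, np.ndarray]
    flags: dict[str, np.ndarray]  # True where fallback applied

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.values[chrom]


def count_genome_patterns(genome: ReferenceGenome) -> dict[str, int]:
    """Count every N-free 5-base window of the genome on the forward strand."""
    return {
        code_to_pattern(i): int(n)
        for i, n in enumerate(_count_codes(genome))
        if n > 0
    }


def _count_codes(genome: ReferenceGenome) -> np.ndarray:
    counts = np.zeros(N_PATTERNS, dtype=np.int64)
    for seq in genome.chromosomes.values():
        codes, valid = _kmer_codes(encode_sequence(seq))
        counts += np.bincount(codes[valid], minlength=N_PATTERNS)
    return counts


def compute_p0(genome: ReferenceGenome, training: MutationDataset) -> ContextTable:
    """Accumulate C' per 5-mer around each training SNV and form P0 = C'/C0.

    InDels and SNVs whose 5-base window touches a chromosome edge or an N
    are excluded from counting and reported in ``skipped_events``.
    Recurrent events (the same site mutated in several strains) contribute
    once per event.
    """
    c0 = _count_codes(genome)
    c_prime = np.zeros(N_PATTERNS, dtype=np.int64)
    skipped = 0
    chrom_codes = {
        chrom: _kmer_codes(encode_sequence(seq))
        for chrom, seq in genome.chromosomes.items()
    }
    snvs = training.snvs()
    for chrom, sub in snvs.groupby("chrom"):
        if chrom not in chrom_codes:
            raise ValueError(f"training record on unknown chromosome {chrom!r}")
        codes, valid = chrom_codes[chrom]
        pos = sub["pos"].to_numpy(dtype=np.int64)
        if (pos < 0).any() or (pos >= len(codes)).any():
            raise ValueError(f"training record beyond chromosome {chrom!r} bounds")
        ok = valid[pos]
        skipped += int((~ok).sum())
        c_prime += np.bincount(codes[pos[ok]], minlength=N_PATTERNS)
    skipped += len(training) - len(snvs)  # InDels
    return ContextTable(c0, c_prime, n_strains=training.n_strains, skipped_events=skipped)


def p0_track(genome: ReferenceGenome, table: ContextTable) -> BaselineTrack:
    """Assign every base the P0 of its centred 5-mer.

    Edge bases, bases in N-containing windows and bases whose pattern is
    unobserved in the table fall back to the central-base marginal and are
    flagged.
    """
    p0 = table.p0
    marg = table.central_base_marginal()
    values: dict[str, np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}
    for chrom, seq in genome.chromosomes.items():
        enc = encode_sequence(seq)
        codes, valid = _kmer_codes(enc)
        v = np.empty(len(enc))
        lookup = np.where(valid, p0[np.where(valid, codes, 0)], np.nan)
        flag = ~valid | np.isnan(lookup)
        central_ok = enc < 4
        fallback = np.where(central_ok, marg[np.minimum(enc, 3)], 0.0)
        v = np.where(flag, fallback, lookup)
        values[chrom] = v
        flags[chrom] = flag
    return BaselineTrack(values, flags)


@dataclass(frozen=True)
class FlankingTestResult:
    """Chi-square test of base composition at one offset from mutated sites."""

    central_base: str
    offset: int
    chi2: float
    p_value: float
    observed: np.ndarray  # counts of A,C,G,T at the offset around mutated sites
    expected: np.ndarray  # genome composition at the offset, scaled to observed total


def flanking_chisq(
    genome: ReferenceGenome,
    training: MutationDataset,
    central_base: str,
    offset: int,
) -> FlankingTestResult:
    """Test whether the base composition at ``offset`` from mutated sites of
    ``central_base`` differs from the genome-wide composition at that offset
    around all sites of the central base.

    Pearson chi-square over the 4 base counts, df = 3, no continuity
    correction.  ``offset`` is in bases relative to the mutated position
    (negative = 5', positive = 3'); sites where the offset leaves the
    chromosome or hits an N are skipped on both sides.
    """
    if central_base not in _BASES:
        raise ValueError(f"central base must be one of A,C,G,T, got {central_base!r}")
    if offset == 0:
        raise ValueError("offset 0 is the mutated base itself")
    b = _BASES.index(central_base)

    observed = np.zeros(4, dtype=np.int64)
    genome_comp = np.zeros(4, dtype=np.int64)
    snvs = training.snvs()
    snvs = snvs[snvs["ref"] == central_base]
    if len(snvs) == 0:
        raise ValueError(f"no mutation events with central base {central_base!r}")
    for chrom, seq in genome.chromosomes.items():
        enc = encode_sequence(seq)
        centers = np.flatnonzero(enc == b)
        neigh = centers + offset
        ok = (neigh >= 0) & (neigh < len(enc))
        nb = enc[neigh[ok]]
        genome_comp += np.bincount(nb[nb < 4], minlength=4)[:4]
        sub = snvs[snvs["chrom"] == chrom]
        if len(sub):
            pos = sub["pos"].to_numpy(dtype=np.int64)
            neigh = pos + offset
            ok = (neigh >= 0) & (neigh < len(enc))
            nb = enc[neigh[ok]]
            observed += np.bincount(nb[nb < 4], minlength=4)[:4]

    total = observed.sum()
    if total == 0:
        raise ValueError("no usable mutation events at this offset")
    if (genome_comp == 0).any():
        raise ValueError("expected count of zero in at least one base cell")
    expected = genome_comp / genome_comp.sum() * total
    chi2, p = stats.chisquare(observed, f_exp=expected)
    return FlankingTestResult(central_base, offset, float(chi2), float(p), observed, expected)
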