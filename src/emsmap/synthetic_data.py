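"""Self-contained synthetic fixtures: genomes, tracks, truth fields, cohorts.

The generator emulates the structure of an EMS mutagenesis experiment so the
whole pipeline is testable without external data.  The ground-truth per-base
per-strain mutation probability is assembled multiplicatively,

    true_p = base_rate * context_multiplier(5-mer) * chromatin_factor,

mirroring the two drivers of mutagenesis bias the pipeline models: local
sequence context (up to ~10-fold spread across 5-mer classes) and chromatin
state (a smooth factor tied to the first signal tracks, with "silent
regions" where the factor collapses to near zero).  The default base rate,
3.6e-6 per base per strain, corresponds to ~360 events per strain on a
100-Mb genome, the scale of a heavily EMS-mutagenized C. elegans cohort;
desk-scale defaults (2-Mb genome, 300 strains) then yield ~2,000 events.

Cohorts are independent Bernoulli(true_p) draws per base per strain.
Mutated G/C bases receive the canonical EMS transition (G->A, C->T) with
probability 0.95.  Screens add one high-impact mutation per selected strain
at a distinct position of a causal gene, plus optional shared background
variants to exercise background removal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter1d

from .context_model import (
    N_PATTERNS,
    _kmer_codes,
    code_to_pattern,
    encode_sequence,
)
from .io_formats import (
    GeneModel,
    MutationDataset,
    ReferenceGenome,
    SignalTrack,
    write_fasta,
    write_genes,
    write_mutations_tsv,
    write_track,
)

_BASES = np.array(list("ACGT"))

_CHROM_NAMES = ["chrI", "chrII", "chrIII", "chrIV", "chrV", "chrX"]

#: EMS chemistry: alkylated guanine mispairs, giving G->A and C->T transitions
EMS_TRANSITION = {"G": "A", "C": "T"}
EMS_TRANSITION_PROB = 0.95

#: impact mix for passenger mutations falling inside genes
_GENIC_IMPACTS = ("missense", "synonymous", "stop_gain", "splicing", "inframe", "other")
_GENIC_IMPACT_P = (0.40, 0.35, 0.06, 0.04, 0.05, 0.10)


def make_genome(
    length: int = 2_000_000,
    n_chroms: int = 1,
    gc_frac: float = 0.36,
    seed: int = 0,
) -> ReferenceGenome:
    """An i.i.d. random genome with the stated G/C fraction.

    The total ``length`` is split evenly across ``n_chroms`` chromosomes
    named like C. elegans chromosomes (chrI, chrII, ...).
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0 < gc_frac < 1:
        raise ValueError("gc_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = np.array(
        [(1 - gc_frac) / 2, gc_frac / 2, gc_frac / 2, (1 - gc_frac) / 2]
    )
    sizes = [length // n_chroms] * n_chroms
    sizes[-1] += length - sum(sizes)
    chroms = {}
    for i, size in enumerate(sizes):
        name = _CHROM_NAMES[i] if i < len(_CHROM_NAMES) else f"chr{i + 1}"
        chroms[name] = "".join(_BASES[rng.choice(4, size=size, p=probs)])
    return ReferenceGenome(chroms)


def make_tracks(
    genome: ReferenceGenome,
    n_tracks: int = 4,
    corr_length: int = 5_000,
    seed: int = 0,
) -> list[SignalTrack]:
    """Smooth chromatin-like signal tracks (Gaussian random fields).

    Each track is white noise smoothed at ``corr_length`` bases (three
    cascaded box filters, a close Gaussian approximation in linear time)
    and standardised, emulating the long-range structure of ChIP signal.
    Only the first tracks drive the truth field (see :func:`make_truth`);
    the rest are uninformative, which exercises feature-importance
    analysis.
    """
    rng = np.random.default_rng(seed)
    tracks = []
    for t in range(n_tracks):
        values = {}
        for chrom, seq in genome.chromosomes.items():
            z = rng.standard_normal(len(seq))
            for _ in range(3):
                # circular padding keeps the field variance uniform along the
                # chromosome (edge-repeat padding would inflate edge variance)
                z = uniform_filter1d(z, size=corr_length, mode="wrap")
            sd = z.std()
            values[chrom] = z / sd if sd > 0 else z
        tracks.append(SignalTrack(f"feat_{t:02d}", values))
    return tracks


@dataclass
class SyntheticTruth:
    """A toy genome with its generating mutation-probability field."""

    genome: ReferenceGenome
    tracks: list[SignalTrack]
    true_p: dict[str, np.ndarray]  # per-base per-strain probability
    context_effects: np.ndarray  # (1024,) multiplier per 5-mer code
    silent_regions: dict[str, list[tuple[int, int]]]
    base_rate: float
    causal_gene: GeneModel | None = None
    seed: int = 0

    def total_p(self) -> float:
        return float(sum(v.sum() for v in self.true_p.values()))

    def expected_events(self, n_strains: int) -> float:
        return n_strains * self.total_p()


def make_truth(
    genome: ReferenceGenome,
    tracks: list[SignalTrack],
    base_rate: float = 3.6e-6,
    context_spread: float = 10.0,
    silent_regions: dict[str, list[tuple[int, int]]] | None = "auto",
    seed: int = 0,
) -> SyntheticTruth:
    """Assemble the ground-truth probability field over a genome.

    Context multipliers are lognormal across 5-mer classes with a
    ~``context_spread``-fold ratio between the 97.5th and 2.5th percentile
    classes, normalised to an occurrence-weighted mean of 1.  The chromatin
    factor is a smooth monotone function of the first two tracks (track 0
    dominant, track 1 secondary), normalised to mean 1.  Silent regions
    (default: one per chromosome, 5 % of its length) have track 0 forced
    low and the factor capped at 0.01, so silent bases satisfy
    ``true_p < 0.1 * base_rate``.  Bases without a complete 5-mer window
    use a context multiplier of 1.
    """
    rng = np.random.default_rng(seed)
    sigma = np.log(context_spread) / (2 * 1.96)
    mult = np.exp(sigma * rng.standard_normal(N_PATTERNS))

    enc = {c: encode_sequence(s) for c, s in genome.chromosomes.items()}
    codes = {c: _kmer_codes(e) for c, e in enc.items()}

    # occurrence-weighted normalisation of the context multipliers
    counts = np.zeros(N_PATTERNS)
    for c in codes:
        cd, ok = codes[c]
        counts += np.bincount(cd[ok], minlength=N_PATTERNS)
    w = counts.sum()
    if w > 0:
        mult /= (mult * counts).sum() / w

    if silent_regions == "auto":
        silent_regions = {}
        for chrom, seq in genome.chromosomes.items():
            L = len(seq)
            s = int(0.60 * L)
            silent_regions[chrom] = [(s, min(L, s + max(L // 20, 1000)))]
    elif silent_regions is None:
        silent_regions = {}

    # force track 0 low inside silent regions so the factor is learnable
    tracks = [
        SignalTrack(t.feature_name, {c: v.copy() for c, v in t.values.items()})
        for t in tracks
    ]
    t0 = tracks[0]
    floor = min(v.min() for v in t0.values.values()) - 1.0
    for chrom, regions in silent_regions.items():
        for s, e in regions:
            t0.values[chrom][s:e] = floor

    def sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    raw_factor = {}
    for chrom in genome.chromosomes:
        f = sigmoid(1.5 * t0.values[chrom])
        if len(tracks) > 1:
            f = f * (0.75 + 0.5 * sigmoid(tracks[1].values[chrom]))
        raw_factor[chrom] = f
    mean_f = np.mean(np.concatenate([raw_factor[c] for c in raw_factor]))
    true_p = {}
    for chrom in genome.chromosomes:
        cd, ok = codes[chrom]
        cmult = np.where(ok, mult[np.where(ok, cd, 0)], 1.0)
        factor = raw_factor[chrom] / mean_f
        for s, e in silent_regions.get(chrom, []):
            factor[s:e] = np.minimum(factor[s:e], 0.01)
        # silent regions are quiet, not absolutely immune: keep a small
        # positive floor so every base retains a nonzero probability
        factor = np.maximum(factor, 1e-4)
        p = base_rate * cmult * factor
        if (p >= 1).any():
            raise ValueError("true_p reaches 1; lower base_rate or spread")
        true_p[chrom] = p
    return SyntheticTruth(
        genome=genome,
        tracks=tracks,
        true_p=true_p,
        context_effects=mult,
        silent_regions=silent_regions,
        base_rate=base_rate,
        seed=seed,
    )


def make_genes(
    genome: ReferenceGenome,
    median_length: int = 2_500,
    length_sigma: float = 0.55,
    mean_gap: int = 500,
    seed: int = 0,
) -> dict[str, GeneModel]:
    """Tile every chromosome with non-overlapping single-interval genes.

    Lengths are lognormal around ``median_length`` (clipped to 0.8-12 kb),
    gaps exponential around ``mean_gap``; strands are random.  The length
    spread matters: gene-level expected counts then span roughly 1-15
    events in a desk-scale screen, a realistic heterogeneity for the
    enrichment test.
    """
    rng = np.random.default_rng(seed)
    genes: dict[str, GeneModel] = {}
    i = 0
    for chrom, seq in genome.chromosomes.items():
        pos = int(rng.exponential(mean_gap)) + 100
        L = len(seq)
        while True:
            glen = int(np.clip(median_length * rng.lognormal(0, length_sigma), 800, 12_000))
            if pos + glen > L - 100:
                break
            gid = f"gene_{i:04d}"
            genes[gid] = GeneModel(
                gid, chrom, [(pos, pos + glen)], "+-"[rng.integers(2)]
            )
            i += 1
            pos += glen + int(rng.exponential(mean_gap)) + 50
    return genes


def _alt_base(ref: str, rng: np.random.Generator) -> str:
    if ref in EMS_TRANSITION and rng.random() < EMS_TRANSITION_PROB:
        return EMS_TRANSITION[ref]
    others = [b for b in "ACGT" if b != ref]
    if ref in EMS_TRANSITION:
        others = [b for b in others if b != EMS_TRANSITION[ref]]
        return others[rng.integers(len(others))]
    return others[rng.integers(len(others))]


def _strain_sets(counts: np.ndarray, n_strains: int, rng: np.random.Generator):
    """For each base index with counts[i] > 0, draw that many distinct strains."""
    hits = np.flatnonzero(counts)
    for i in hits:
        yield i, rng.choice(n_strains, size=counts[i], replace=False)


def simulate_cohort(
    truth: SyntheticTruth,
    n_strains: int,
    seed: int = 0,
    genes: dict[str, GeneModel] | None = None,
    batch_label: str = "cohort",
    strain_prefix: str = "s",
) -> MutationDataset:
    """Bernoulli-mutagenize ``n_strains`` independent strains.

    Per-base event counts are Binomial(n_strains, true_p) and the carrying
    strains are drawn without replacement, which is equivalent to
    independent per-strain Bernoulli draws.  Alt alleles follow EMS
    transition chemistry.  When ``genes`` is given, events inside genes get
    a genic impact annotation (missense/synonymous/...); other events are
    intergenic.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    rng = np.random.default_rng(seed)
    strains = [f"{strain_prefix}{i:04d}" for i in range(n_strains)]

    gene_lookup: dict[str, np.ndarray] = {}
    if genes:
        for chrom, seq in truth.genome.chromosomes.items():
            mask = np.zeros(len(seq), dtype=bool)
            for g in genes.values():
                if g.chrom == chrom:
                    for s, e in g.intervals:
                        mask[s:e] = True
            gene_lookup[chrom] = mask

    rows = []
    for chrom, p in truth.true_p.items():
        counts = rng.binomial(n_strains, p)
        seq = truth.genome[chrom]
        genic = gene_lookup.get(chrom)
        for pos, strain_idx in _strain_sets(counts, n_strains, rng):
            ref = seq[pos]
            if ref == "N":
                continue
            for si in strain_idx:
                alt = _alt_base(ref, rng)
                if genic is not None and genic[pos]:
                    impact = rng.choice(_GENIC_IMPACTS, p=_GENIC_IMPACT_P)
                elif genic is not None:
                    impact = "intergenic"
                else:
                    impact = None
                rows.append((strains[si], chrom, int(pos), ref, alt, "SNV", impact))
    import pandas as pd

    df = pd.DataFrame(
        rows, columns=["strain", "chrom", "pos", "ref", "alt", "variant_class", "impact"]
    )
    return MutationDataset(df, batch_label=batch_label, n_strains=n_strains)


def simulate_screen(
    truth: SyntheticTruth,
    causal_gene: GeneModel,
    n_selected: int = 38,
    high_impact_classes: tuple[str, ...] = ("stop_gain", "missense", "splicing", "InDel"),
    n_background: int = 0,
    background_share: float = 0.3,
    seed: int = 0,
    genes: dict[str, GeneModel] | None = None,
    batch_label: str = "screen",
) -> MutationDataset:
    """A phenotype-selected pool: every strain carries one causal-gene hit.

    Each selected strain receives one high-impact mutation at a distinct
    random position of ``causal_gene`` (class drawn from
    ``high_impact_classes``) on top of its Bernoulli passenger mutations.
    ``n_background`` shared variants are each injected into
    ``background_share`` of the strains to exercise background removal.
    """
    span = causal_gene.span
    sizes = truth.genome.chrom_sizes()
    if causal_gene.chrom not in sizes or span[1] > sizes[causal_gene.chrom]:
        raise ValueError("causal gene lies outside the genome")
    rng = np.random.default_rng(seed)
    pool = simulate_cohort(
        truth,
        n_selected,
        seed=int(rng.integers(2**31 - 1)),
        genes=genes,
        batch_label=batch_label,
        strain_prefix="sup",
    )
    strains = [f"sup{i:04d}" for i in range(n_selected)]
    seq = truth.genome[causal_gene.chrom]

    gene_positions = np.concatenate(
        [np.arange(s, e) for s, e in causal_gene.intervals]
    )
    causal_pos = rng.choice(gene_positions, size=n_selected, replace=False)
    rows = []
    for strain, pos in zip(strains, causal_pos):
        cls = high_impact_classes[rng.integers(len(high_impact_classes))]
        ref = seq[pos]
        if ref == "N":
            ref = "G"
        if cls == "InDel":
            rows.append((strain, causal_gene.chrom, int(pos), ref, ref + "A", "InDel", None))
        else:
            rows.append((strain, causal_gene.chrom, int(pos), ref, _alt_base(ref, rng), "SNV", cls))

    n_carriers = max(2, int(np.ceil(background_share * n_selected)))
    chroms = list(truth.genome.chromosomes)
    for _ in range(n_background):
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(2, sizes[chrom] - 2))
        ref = truth.genome[chrom][pos]
        if ref == "N":
            continue
        alt = _alt_base(ref, rng)
        for si in rng.choice(n_selected, size=n_carriers, replace=False):
            rows.append((strains[si], chrom, pos, ref, alt, "SNV", "intergenic" if genes else None))

    import pandas as pd

    extra = pd.DataFrame(
        rows, columns=["strain", "chrom", "pos", "ref", "alt", "variant_class", "impact"]
    )
    df = pd.concat([pool.df[extra.columns], extra], ignore_index=True)
    return MutationDataset(df, batch_label=batch_label, n_strains=n_selected)


def export_fixtures(
    truth: SyntheticTruth,
    outdir: str | Path,
    genes: dict[str, GeneModel] | None = None,
    cohort: MutationDataset | None = None,
) -> None:
    """Write a truth bundle to standard text formats (FASTA, bedGraph, GFF3,
    TSV, JSON) so it can be re-ingested through :mod:`emsmap.io_formats`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(truth.genome, outdir / "genome.fa")
    for t in truth.tracks:
        write_track(t, outdir / f"{t.feature_name}.bedgraph")
    write_track(
        SignalTrack("true_p", truth.true_p), outdir / "true_p.bedgraph"
    )
    if genes:
        write_genes(genes, outdir / "genes.gff3")
    if cohort is not None:
        write_mutations_tsv(cohort, outdir / f"{cohort.batch_label}.tsv")
    meta = {
        "base_rate": truth.base_rate,
        "seed": truth.seed,
        "silent_regions": truth.silent_regions,
        "context_effects": {
            code_to_pattern(i): float(m) for i, m in enumerate(truth.context_effects)
        },
    }
    (outdir / "truth.json").write_text(json.dumps(meta, indent=1))
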