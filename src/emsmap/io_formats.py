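"""Shared domain types and readers/writers for the standard formats.

The pipeline touches FASTA (reference genome), VCF 4.x and MMP-style TSV
(mutation catalogues), bedGraph / wiggle (DNA-binding-protein signal and
probability maps) and GFF3 (gene models).  All coordinates are 0-based
half-open internally; conversion to and from the 1-based conventions of
VCF, GFF3 and wiggle happens only in this module.

Mutation catalogues are held in a :class:`MutationDataset`, a thin wrapper
around a :class:`pandas.DataFrame` with one row per mutation event.  VCF
input is filtered on read with the strict ``depth > min_depth`` and
``allele_freq > min_af`` rules used for screen sequencing; MMP-style TSV
catalogues are assumed curated and pass through unfiltered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

#: canonical columns of the mutation table backing a MutationDataset
MUTATION_COLUMNS = [
    "strain",
    "chrom",
    "pos",  # 0-based
    "ref",
    "alt",
    "variant_class",
    "impact",
    "depth",
    "allele_freq",
]

IMPACT_CLASSES = (
    "missense",
    "stop_gain",
    "splicing",
    "inframe",
    "synonymous",
    "intergenic",
    "other",
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ReferenceGenome:
    """An ordered set of named chromosome sequences over {A,C,G,T,N}."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"chromosome {name!r} has invalid bases {sorted(bad)}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __getitem__(self, chrom: str) -> str:
        return self.chromosomes[chrom]


@dataclass(frozen=True)
class MutationRecord:
    """A single mutation event in one strain."""

    strain_id: str
    chrom: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str
    variant_class: str = "SNV"  # {SNV, InDel}
    impact: str | None = None
    depth: int | None = None
    allele_freq: float | None = None

    def __post_init__(self) -> None:
        is_snv = len(self.ref_base) == 1 and len(self.alt_base) == 1
        if is_snv != (self.variant_class == "SNV"):
            raise ValueError(
                f"variant_class {self.variant_class!r} inconsistent with "
                f"alleles {self.ref_base}>{self.alt_base}"
            )


def classify_variant(ref: str, alt: str) -> str:
    return "SNV" if len(ref) == 1 and len(alt) == 1 else "InDel"


class MutationDataset:
    """A cohort's mutation events with strain identities.

    Parameters
    ----------
    df
        One row per mutation event with the columns of
        :data:`MUTATION_COLUMNS` (missing optional columns are added as NA).
        Positions are 0-based.
    batch_label
        Identifier of the mutagenesis batch (e.g. ``"MMP"``).
    n_strains
        Number of strains in the cohort.  Defaults to the number of distinct
        strain ids in ``df``; pass explicitly when some strains carry no
        surviving events.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        batch_label: str = "batch",
        n_strains: int | None = None,
    ) -> None:
        df = df.copy()
        for col in MUTATION_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        self.df = df[MUTATION_COLUMNS].reset_index(drop=True)
        self.batch_label = batch_label
        observed = self.df["strain"].nunique()
        if n_strains is None:
            n_strains = observed
        if n_strains < 1:
            raise ValueError("a cohort needs at least one strain")
        if observed > n_strains:
            raise ValueError(
                f"{observed} distinct strain ids exceed declared n_strains={n_strains}"
            )
        self.n_strains = int(n_strains)

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[MutationRecord]:
        for row in self.df.itertuples(index=False):
            yield MutationRecord(
                strain_id=row.strain,
                chrom=row.chrom,
                pos=int(row.pos),
                ref_base=row.ref,
                alt_base=row.alt,
                variant_class=row.variant_class,
                impact=None if pd.isna(row.impact) else row.impact,
                depth=None if pd.isna(row.depth) else int(row.depth),
                allele_freq=None if pd.isna(row.allele_freq) else float(row.allele_freq),
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[MutationRecord],
        batch_label: str = "batch",
        n_strains: int | None = None,
    ) -> "MutationDataset":
        rows = [
            (r.strain_id, r.chrom, r.pos, r.ref_base, r.alt_base,
             r.variant_class, r.impact, r.depth, r.allele_freq)
            for r in records
        ]
        df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
        return cls(df, batch_label=batch_label, n_strains=n_strains)

    # -- views --------------------------------------------------------------

    def snvs(self) -> pd.DataFrame:
        return self.df[self.df["variant_class"] == "SNV"]

    def events_per_strain(self) -> float:
        """Mean number of mutation events per strain in the cohort."""
        return len(self.df) / self.n_strains

    def validate_against(self, genome: ReferenceGenome) -> None:
        """Check positions and SNV reference alleles against ``genome``."""
        sizes = genome.chrom_sizes()
        for row in self.df.itertuples(index=False):
            if row.chrom not in sizes:
                raise ValueError(f"record at {row.chrom}:{row.pos + 1} on unknown chromosome")
            if not (0 <= row.pos < sizes[row.chrom]):
                raise ValueError(
                    f"record {row.strain} {row.chrom}:{row.pos + 1} beyond chromosome "
                    f"length {sizes[row.chrom]}"
                )
            if row.variant_class == "SNV":
                actual = genome[row.chrom][row.pos]
                if actual != row.ref and actual != "N":
                    raise ValueError(
                        f"record {row.strain} {row.chrom}:{row.pos + 1} ref {row.ref!r} "
                        f"does not match genome base {actual!r}"
                    )

    def subset_strains(self, strains: Sequence[str]) -> "MutationDataset":
        keep = self.df[self.df["strain"].isin(strains)]
        return MutationDataset(keep, batch_label=self.batch_label, n_strains=len(strains))


@dataclass
class GeneModel:
    """A gene territory: sorted non-overlapping intervals on one chromosome.

    Intervals are 0-based half-open.  The default territory is the annotated
    gene body; exon-only territories use the same type.
    """

    gene_id: str
    chrom: str
    intervals: list[tuple[int, int]]
    strand: str = "+"

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals)
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(f"gene {self.gene_id}: overlapping intervals")
        for s, e in ivs:
            if not (0 <= s < e):
                raise ValueError(f"gene {self.gene_id}: bad interval ({s}, {e})")
        self.intervals = ivs
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def span(self) -> tuple[int, int]:
        return self.intervals[0][0], self.intervals[-1][1]

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.intervals)


@dataclass
class SignalTrack:
    """Per-base float signal of one DNA-binding feature, raw or smoothed."""

    feature_name: str
    values: dict[str, np.ndarray]
    smoothed: bool = False
    window: int | None = None

    def __post_init__(self) -> None:
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    def padded_to(self, chrom_sizes: Mapping[str, int]) -> "SignalTrack":
        """Return a copy covering every chromosome, zero-padded/truncated."""
        out = {}
        for chrom, size in chrom_sizes.items():
            v = self.values.get(chrom, np.zeros(0))
            if len(v) < size:
                v = np.concatenate([v, np.zeros(size - len(v))])
            out[chrom] = v[:size]
        return SignalTrack(self.feature_name, out, self.smoothed, self.window)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read a (possibly line-wrapped) FASTA file into a ReferenceGenome.

    Sequences are uppercased; chromosome names are the header up to the
    first whitespace.  Duplicate names and empty files are errors.
    """
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in chroms:
            raise FormatError(f"duplicate chromosome name {name!r} in {path}")
        chroms[name] = str(rec.seq).upper()
    if not chroms:
        raise FormatError(f"no FASTA records found in {path}")
    return ReferenceGenome(chroms)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# mutation catalogues
# ---------------------------------------------------------------------------

_MMP_BASE_COLS = ["strain", "chrom", "pos", "ref", "alt"]


def _read_mmp_tsv(path: str | Path) -> pd.DataFrame:
    """MMP-style TSV: strain, chrom, pos(1-based), ref, alt[, annotation]."""
    first = open(path).readline()
    has_header = first.lstrip("#").lower().startswith("strain")
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        comment=None if has_header else "#",
        dtype=str,
    )
    if df.shape[1] < 5:
        raise FormatError(f"{path}: expected at least 5 tab-separated columns")
    ncol = min(df.shape[1], 6)
    df = df.iloc[:, :ncol]
    df.columns = (_MMP_BASE_COLS + ["impact"])[:ncol]
    if "impact" not in df.columns:
        df["impact"] = pd.NA
    df["pos"] = df["pos"].astype(int) - 1  # to 0-based
    df["ref"] = df["ref"].str.upper()
    df["alt"] = df["alt"].str.upper()
    df["variant_class"] = [classify_variant(r, a) for r, a in zip(df["ref"], df["alt"])]
    df["depth"] = pd.NA
    df["allele_freq"] = pd.NA
    return df[MUTATION_COLUMNS]


def _vcf_records(path: str | Path, strain_id: str | None) -> Iterator[dict]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if strain_id is None:
        strain_id = samples[0] if len(samples) == 1 else Path(path).stem
    for v in vcf:
        alt = v.ALT[0] if v.ALT else None
        if alt is None:
            continue
        depth = v.INFO.get("DP")
        af = v.INFO.get("AF")
        if isinstance(af, tuple):
            af = af[0]
        if af is not None:
            # htslib stores AF as float32; round away representation noise so
            # a written "0.8" compares as exactly 0.8 under the strict filter
            af = round(float(af), 6)
        if depth is None and len(samples) >= 1:
            try:
                depth = int(v.gt_depths[0])
                if depth < 0:
                    depth = None
            except Exception:
                depth = None
        if af is None and len(samples) >= 1:
            try:
                ad = v.gt_alt_depths[0]
                dp = v.gt_depths[0]
                if ad >= 0 and dp > 0:
                    af = ad / dp
            except Exception:
                af = None
        yield {
            "strain": strain_id,
            "chrom": v.CHROM,
            "pos": v.POS - 1,
            "ref": v.REF.upper(),
            "alt": str(alt).upper(),
            "variant_class": classify_variant(v.REF, str(alt)),
            "impact": None,
            "depth": depth,
            "allele_freq": af,
        }


def read_mutations(
    path: str | Path,
    format: str = "mmp_tsv",
    min_depth: int = 5,
    min_af: float = 0.8,
    genome: ReferenceGenome | None = None,
    strain_id: str | None = None,
    batch_label: str | None = None,
) -> MutationDataset:
    """Read a mutation catalogue from MMP-style TSV or single-strain VCF.

    VCF records are kept only when ``depth > min_depth`` **and**
    ``allele_freq > min_af`` (strict inequalities, the filter used on screen
    sequencing); records with missing depth or allele frequency are dropped
    with a warning.  MMP-style TSV catalogues pass through unfiltered.
    """
    if format == "mmp_tsv":
        df = _read_mmp_tsv(path)
    elif format == "vcf":
        rows = list(_vcf_records(path, strain_id))
        df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
        n_missing = int(df["depth"].isna().sum() + df["allele_freq"].isna().sum())
        if n_missing:
            logger.warning(
                "%s: dropping records with missing DP/AF (cannot verify filter)", path
            )
        df = df.dropna(subset=["depth", "allele_freq"])
        df = df[(df["depth"] > min_depth) & (df["allele_freq"] > min_af)]
    else:
        raise ValueError(f"unknown mutation format {format!r}")
    # a fully filtered single-strain file is still a one-strain cohort
    ds = MutationDataset(
        df,
        batch_label=batch_label or Path(path).stem,
        n_strains=max(1, df["strain"].nunique()),
    )
    if genome is not None:
        ds.validate_against(genome)
    return ds


def read_mutation_pool(
    paths: Sequence[str | Path],
    format: str = "vcf",
    batch_label: str = "pool",
    **kwargs,
) -> MutationDataset:
    """Read one file per strain and pool them into a single dataset."""
    parts = [read_mutations(p, format=format, **kwargs) for p in paths]
    df = pd.concat([p.df for p in parts], ignore_index=True)
    return MutationDataset(df, batch_label=batch_label, n_strains=len(paths))


def write_mutations_tsv(dataset: MutationDataset, path: str | Path) -> None:
    """Write an MMP-style TSV (1-based positions, optional annotation column)."""
    out = dataset.df[["strain", "chrom", "pos", "ref", "alt", "impact"]].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# signal tracks (bedGraph / wiggle)
# ---------------------------------------------------------------------------


def _sniff_track_format(path: str | Path) -> str:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                return "wiggle"
            return "bedgraph"
    raise FormatError(f"{path}: empty track file")


def read_track(
    path: str | Path,
    format: str | None = None,
    feature_name: str | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> SignalTrack:
    """Read a bedGraph or wiggle file into a dense per-base SignalTrack.

    Bases not covered by any interval are 0.0.  bedGraph intervals must be
    sorted and non-overlapping within each chromosome.  Without
    ``chrom_sizes`` each chromosome array extends to its last covered base.
    """
    if format is None:
        format = _sniff_track_format(path)
    intervals: dict[str, list[tuple[int, int, float]]] = {}

    def add(chrom: str, start: int, end: int, value: float) -> None:
        intervals.setdefault(chrom, []).append((start, end, value))

    with open(path) as fh:
        if format == "bedgraph":
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                parts = line.split()
                if len(parts) != 4:
                    raise FormatError(f"{path}:{ln}: expected 4 bedGraph columns")
                add(parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
        elif format == "wiggle":
            mode = None
            chrom = None
            step = span = 1
            nxt = 0
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                if line.startswith(("fixedStep", "variableStep")):
                    fields = dict(kv.split("=") for kv in line.split()[1:])
                    chrom = fields["chrom"]
                    span = int(fields.get("span", 1))
                    if line.startswith("fixedStep"):
                        mode = "fixed"
                        nxt = int(fields["start"]) - 1  # to 0-based
                        step = int(fields.get("step", 1))
                    else:
                        mode = "variable"
                    continue
                if mode == "fixed":
                    add(chrom, nxt, nxt + span, float(line))
                    nxt += step
                elif mode == "variable":
                    p, v = line.split()
                    start = int(p) - 1
                    add(chrom, start, start + span, float(v))
                else:
                    raise FormatError(f"{path}:{ln}: data before wiggle header")
        else:
            raise ValueError(f"unknown track format {format!r}")

    values: dict[str, np.ndarray] = {}
    for chrom, ivs in intervals.items():
        prev_end = -1
        prev_start = -1
        for start, end, _ in ivs:
            if start < prev_start:
                raise FormatError(f"{path}: unsorted intervals on {chrom}")
            if start < prev_end:
                raise FormatError(f"{path}: overlapping intervals on {chrom}")
            if end <= start:
                raise FormatError(f"{path}: empty interval on {chrom}")
            prev_start, prev_end = start, end
        size = chrom_sizes[chrom] if chrom_sizes else ivs[-1][1]
        arr = np.zeros(size)
        for start, end, value in ivs:
            arr[start:min(end, size)] = value
        values[chrom] = arr
    if feature_name is None:
        feature_name = Path(path).stem
    return SignalTrack(feature_name, values)


def write_track(track: SignalTrack | "object", path: str | Path) -> None:
    """Write per-base values as bedGraph, run-length merging equal neighbours.

    Accepts a :class:`SignalTrack` or any object with a ``values`` mapping of
    chromosome name to per-base array (e.g. a probability map).
    """
    with open(path, "w") as fh:
        for chrom, arr in track.values.items():
            arr = np.asarray(arr, dtype=float)
            if len(arr) == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:.10g}\n")


# write_probability_map is the same serialization; see maps.MutProbMap.values
write_probability_map = write_track


# ---------------------------------------------------------------------------
# gene models (GFF3)
# ---------------------------------------------------------------------------


def read_genes(
    path: str | Path,
    exons_only: bool = False,
    feature_type: str = "gene",
) -> dict[str, GeneModel]:
    """Read gene models from GFF3.

    The default gene territory is the annotated gene body (one interval);
    with ``exons_only`` the territory is the union of the gene's exons.
    """
    import gffutils

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type(feature_type):
        gene_id = g.attributes.get("ID", [g.id])[0]
        if exons_only:
            ivs = [(e.start - 1, e.end) for e in db.children(g, featuretype="exon")]
            ivs = _merge_intervals(ivs) or [(g.start - 1, g.end)]
        else:
            ivs = [(g.start - 1, g.end)]
        genes[gene_id] = GeneModel(gene_id, g.seqid, ivs, g.strand if g.strand in "+-" else "+")
    if not genes:
        raise FormatError(f"no {feature_type!r} features found in {path}")
    return genes


def write_genes(genes: Mapping[str, GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal GFF3 (gene + exon rows per interval)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.values():
            s, e = g.span
            fh.write(
                f"{g.chrom}\temsmap\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(g.intervals, 1):
                fh.write(
                    f"{g.chrom}\temsmap\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}\n"
                )


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]
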