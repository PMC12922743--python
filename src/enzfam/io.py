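"""Tabular genomic I/O with fixed coordinate conventions.

All intervals are held internally as 0-based, half-open ``[start, end)``.
BED-like inputs are native; SEG (1-based, inclusive) and VCF-style positions
are converted at the boundary and converted back on write.  Files are UTF-8,
tab-delimited, with ``.`` for missing values and a fixed column order per
format so that write→read round-trips are byte-stable.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

MISSING = "."

#: The seven first-level UniProt enzyme classes.
ENZYME_CLASSES = (
    "oxidoreductases",
    "transferases",
    "hydrolases",
    "lyases",
    "isomerases",
    "ligases",
    "translocases",
)

#: The eleven admitted enzyme families (oxygenase excluded for redundancy
#: with oxidoreductase).
ENZYME_FAMILIES = (
    "glycosidase",
    "g_protein",
    "kinase",
    "lipase",
    "methyltransferase",
    "oxidoreductase",
    "phosphatase",
    "protease",
    "transaminase",
    "helicase",
    "nuclease",
)

VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "splice_site",
    "frameshift_del",
    "inframe",
    "silent",
    "other",
)

#: Variant classes counted as deleterious by the recurrence rule.
DELETERIOUS_CLASSES = frozenset(
    {"missense", "nonsense", "splice_site", "frameshift_del"}
)

SV_TYPES = ("DEL", "DUP", "INV", "TRA")


class FormatError(ValueError):
    """A file violated its declared schema or an invariant."""


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with optional enzyme class/family annotation.

    The permutation machinery samples genes as units; ``length_bp`` is the
    coverage contribution of the gene.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    enzyme_class: str | None = None
    enzyme_family: str | None = None
    is_cgc: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.enzyme_family is not None and self.enzyme_family not in ENZYME_FAMILIES:
            raise FormatError(
                f"gene {self.gene_id}: unknown enzyme family "
                f"{self.enzyme_family!r}; admitted: {', '.join(ENZYME_FAMILIES)}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MutationEvent:
    sample_id: str
    gene_id: str
    variant_class: str
    chrom: str | None = None
    pos: int | None = None  # 1-based, VCF-style

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise FormatError(
                f"unknown variant class {self.variant_class!r}; "
                f"admitted: {', '.join(VARIANT_CLASSES)}"
            )

    @property
    def is_deleterious(self) -> bool:
        return self.variant_class in DELETERIOUS_CLASSES


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # 0-based half-open
    end: int
    value: float  # logR, or total copy number for allele_specific

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(f"invalid segment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentProfile:
    """Per-sample copy-number segmentation in one of two dialects.

    ``logr`` carries SEG-style log ratios; ``allele_specific`` carries integer
    total copy number together with a per-sample ploidy (and optional purity).
    """

    sample_id: str
    dialect: str  # "logr" | "allele_specific"
    segments: list[Segment]
    ploidy: float | None = None
    purity: float | None = None
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dialect not in ("logr", "allele_specific"):
            raise FormatError(f"unknown dialect {self.dialect!r}")
        if self.dialect == "allele_specific":
            if self.ploidy is None:
                raise FormatError(
                    f"sample {self.sample_id}: allele_specific profile requires ploidy"
                )
            for seg in self.segments:
                if seg.value < 0:
                    raise FormatError(
                        f"sample {self.sample_id}: negative total_cn {seg.value}"
                    )
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start))
        self._check_overlaps()
        if not self.chrom_lengths:
            self.chrom_lengths = {}
            for seg in self.segments:
                self.chrom_lengths[seg.chrom] = max(
                    self.chrom_lengths.get(seg.chrom, 0), seg.end
                )
        for seg in self.segments:
            if seg.end > self.chrom_lengths.get(seg.chrom, 0):
                raise FormatError(
                    f"sample {self.sample_id}: segment ends at {seg.end} beyond "
                    f"{seg.chrom} length {self.chrom_lengths.get(seg.chrom)}"
                )

    def _check_overlaps(self) -> None:
        prev: Segment | None = None
        for seg in self.segments:
            if prev is not None and seg.chrom == prev.chrom and seg.start < prev.end:
                raise FormatError(
                    f"sample {self.sample_id}: overlapping segments on {seg.chrom}: "
                    f"[{prev.start},{prev.end}) and [{seg.start},{seg.end})"
                )
            prev = seg

    def chrom_segments(self, chrom: str) -> list[Segment]:
        return [s for s in self.segments if s.chrom == chrom]


@dataclass(frozen=True)
class StructuralVariant:
    sample_id: str
    sv_type: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    homology_len_nt: int = 0

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise FormatError(f"unknown sv_type {self.sv_type!r}")
        if self.homology_len_nt < 0:
            raise FormatError("homology length must be >= 0")

    @property
    def size_bp(self) -> int | None:
        """Event size; undefined (None) for interchromosomal events."""
        if self.chrom1 != self.chrom2:
            return None
        return abs(self.pos2 - self.pos1)


@dataclass(frozen=True)
class IndelRecord:
    sample_id: str
    kind: str  # "deletion" | "insertion"
    length_nt: int

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion"):
            raise FormatError(f"unknown indel kind {self.kind!r}")
        if self.length_nt < 1:
            raise FormatError(f"indel length must be >= 1, got {self.length_nt}")


# ---------------------------------------------------------------------------
# gene universe (BED-like TSV)

_GENE_COLS = ["chrom", "start", "end", "gene_id", "enzyme_class", "enzyme_family", "cgc"]


def read_gene_universe(path: str | Path) -> list[GeneModel]:
    """Read a BED-like gene TSV (0-based half-open coordinates).

    Required columns: chrom, start, end, gene_id; optional: enzyme_class,
    enzyme_family, cgc.  Raises :class:`FormatError` with the offending line
    number on invalid intervals and names the duplicate on repeated gene ids.
    """
    df = _read_tsv(path, required=["chrom", "start", "end", "gene_id"])
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gid = str(row.gene_id)
        if gid in seen:
            raise FormatError(f"{path}: duplicate gene_id {gid!r}")
        seen.add(gid)
        start, end = int(row.start), int(row.end)
        if start >= end:
            raise FormatError(f"{path} line {i}: start {start} >= end {end}")
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=str(row.chrom),
                start=start,
                end=end,
                enzyme_class=_opt(getattr(row, "enzyme_class", MISSING)),
                enzyme_family=_opt(getattr(row, "enzyme_family", MISSING)),
                is_cgc=_as_bool(getattr(row, "cgc", 0)),
            )
        )
    return genes


def write_gene_universe(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        (
            g.chrom,
            g.start,
            g.end,
            g.gene_id,
            g.enzyme_class or MISSING,
            g.enzyme_family or MISSING,
            int(g.is_cgc),
        )
        for g in genes
    ]
    pd.DataFrame(rows, columns=_GENE_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# segments

_SEG_COLS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def read_segments(
    path: str | Path,
    dialect: str,
    chrom_lengths: dict[str, int] | None = None,
) -> list[SegmentProfile]:
    """Read segment profiles.

    ``logr`` expects standard SEG (1-based inclusive; converted to 0-based
    half-open internally).  ``allele_specific`` expects a TSV with columns
    sample, chrom, start, end, total_cn (already 0-based half-open) preceded
    by ``##sample=<id>\tploidy=<x>[\tpurity=<y>]`` metadata lines and optional
    ``##contig=<chrom>\tlength=<bp>`` lines.
    """
    if dialect == "logr":
        df = _read_tsv(path, required=_SEG_COLS).rename(
            columns={"loc.start": "loc_start", "loc.end": "loc_end", "seg.mean": "seg_mean"}
        )
        profiles = []
        for sid, grp in df.groupby("ID", sort=True):
            segs = [
                Segment(str(r.chrom), int(r.loc_start) - 1, int(r.loc_end), float(r.seg_mean))
                for r in grp.itertuples(index=False)
            ]
            profiles.append(
                SegmentProfile(str(sid), "logr", segs, chrom_lengths=dict(chrom_lengths or {}))
            )
        return profiles
    if dialect == "allele_specific":
        meta: dict[str, dict[str, float]] = {}
        contigs: dict[str, int] = dict(chrom_lengths or {})
        body_lines: list[str] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("##sample="):
                    parts = dict(
                        p.split("=", 1) for p in line[2:].rstrip("\n").split("\t")
                    )
                    meta[parts["sample"]] = {
                        k: float(v) for k, v in parts.items() if k != "sample"
                    }
                elif line.startswith("##contig="):
                    parts = dict(
                        p.split("=", 1) for p in line[2:].rstrip("\n").split("\t")
                    )
                    contigs[parts["contig"]] = int(parts["length"])
                else:
                    body_lines.append(line)
        df = _read_tsv(
            _io.StringIO("".join(body_lines)),
            required=["sample", "chrom", "start", "end", "total_cn"],
        )
        profiles = []
        for sid, grp in df.groupby("sample", sort=True):
            sid = str(sid)
            if sid not in meta:
                raise FormatError(f"{path}: sample {sid} has no ploidy metadata")
            segs = [
                Segment(str(r.chrom), int(r.start), int(r.end), float(r.total_cn))
                for r in grp.itertuples(index=False)
            ]
            profiles.append(
                SegmentProfile(
                    sid,
                    "allele_specific",
                    segs,
                    ploidy=meta[sid]["ploidy"],
                    purity=meta[sid].get("purity"),
                    chrom_lengths=dict(contigs),
                )
            )
        return profiles
    raise FormatError(f"unknown dialect {dialect!r}")


def write_segments(profiles: Sequence[SegmentProfile], path: str | Path) -> None:
    """Write profiles in the dialect they carry (all must share one)."""
    dialects = {p.dialect for p in profiles}
    if len(dialects) != 1:
        raise FormatError(f"mixed dialects in one file: {sorted(dialects)}")
    dialect = dialects.pop()
    if dialect == "logr":
        rows = [
            (p.sample_id, s.chrom, s.start + 1, s.end, s.length, s.value)
            for p in profiles
            for s in p.segments
        ]
        pd.DataFrame(rows, columns=_SEG_COLS).to_csv(path, sep="\t", index=False)
        return
    with open(path, "w", encoding="utf-8") as fh:
        contigs: dict[str, int] = {}
        for p in profiles:
            contigs.update(p.chrom_lengths)
        for chrom in sorted(contigs):
            fh.write(f"##contig={chrom}\tlength={contigs[chrom]}\n")
        for p in sorted(profiles, key=lambda q: q.sample_id):
            line = f"##sample={p.sample_id}\tploidy={p.ploidy}"
            if p.purity is not None:
                line += f"\tpurity={p.purity}"
            fh.write(line + "\n")
        fh.write("sample\tchrom\tstart\tend\ttotal_cn\n")
        for p in sorted(profiles, key=lambda q: q.sample_id):
            for s in p.segments:
                fh.write(
                    f"{p.sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t{int(s.value)}\n"
                )


# ---------------------------------------------------------------------------
# mutations (minimal MAF-like TSV)

_MUT_COLS = ["sample", "gene", "chrom", "pos", "ref", "alt", "variant_class"]


def read_mutations(path: str | Path) -> list[MutationEvent]:
    df = _read_tsv(path, required=["sample", "gene", "variant_class"])
    events = []
    for r in df.itertuples(index=False):
        pos = getattr(r, "pos", MISSING)
        events.append(
            MutationEvent(
                sample_id=str(r.sample),
                gene_id=str(r.gene),
                variant_class=str(r.variant_class),
                chrom=_opt(getattr(r, "chrom", MISSING)),
                pos=None if _opt(pos) is None else int(pos),
            )
        )
    return events


def write_mutations(events: Iterable[MutationEvent], path: str | Path) -> None:
    rows = [
        (
            e.sample_id,
            e.gene_id,
            e.chrom or MISSING,
            MISSING if e.pos is None else e.pos,
            MISSING,
            MISSING,
            e.variant_class,
        )
        for e in events
    ]
    pd.DataFrame(rows, columns=_MUT_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SVs (BEDPE + svtype/homlen extension) and indels

_BEDPE_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "svtype", "homlen",
]


def read_bedpe(path: str | Path) -> list[StructuralVariant]:
    """BEDPE with svtype/homlen extension columns; ``name`` is the sample id."""
    df = _read_tsv(
        path, required=["chrom1", "start1", "chrom2", "start2", "name", "svtype", "homlen"]
    )
    svs = []
    for r in df.itertuples(index=False):
        homlen = int(r.homlen)
        if homlen < 0:
            raise FormatError(f"{path}: negative homlen {homlen}")
        chrom1, chrom2 = str(r.chrom1), str(r.chrom2)
        svtype = str(r.svtype)
        if chrom1 != chrom2:
            svtype = "TRA"
        svs.append(
            StructuralVariant(
                sample_id=str(r.name),
                sv_type=svtype,
                chrom1=chrom1,
                pos1=int(r.start1),
                chrom2=chrom2,
                pos2=int(r.start2),
                homology_len_nt=homlen,
            )
        )
    return svs


def write_bedpe(svs: Iterable[StructuralVariant], path: str | Path) -> None:
    rows = [
        (
            s.chrom1, s.pos1, s.pos1 + 1, s.chrom2, s.pos2, s.pos2 + 1,
            s.sample_id, MISSING, MISSING, MISSING, s.sv_type, s.homology_len_nt,
        )
        for s in svs
    ]
    pd.DataFrame(rows, columns=_BEDPE_COLS).to_csv(path, sep="\t", index=False)


def read_indels(path: str | Path) -> list[IndelRecord]:
    df = _read_tsv(path, required=["sample", "kind", "length"])
    return [
        IndelRecord(str(r.sample), str(r.kind), int(r.length))
        for r in df.itertuples(index=False)
    ]


def write_indels(indels: Iterable[IndelRecord], path: str | Path) -> None:
    rows = [(i.sample_id, i.kind, i.length_nt) for i in indels]
    pd.DataFrame(rows, columns=["sample", "kind", "length"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# generic schema'd table

def read_table(path: str | Path, schema: Sequence[str]) -> pd.DataFrame:
    """Read a TSV requiring the schema columns; extras are preserved."""
    return _read_tsv(path, required=list(schema))


# ---------------------------------------------------------------------------
# helpers

def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "chrom1": str, "chrom2": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value)
    return None if s in (MISSING, "", "nan") else s


def _as_bool(value) -> bool:
    if _opt(value) is None:
        return False
    return str(value) in ("1", "True", "true")
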