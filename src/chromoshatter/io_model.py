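"""Domain types and file I/O for SV, copy-number, SNV and gene inputs.

Internal coordinate convention is 1-based inclusive throughout (the seg/VCF
convention). BEDPE is read as 0-based half-open and each breakpoint is
collapsed to the end coordinate of its interval, i.e. the 1-based position of
the last base of the breakpoint interval. Intrachromosomal records are
normalised so that pos1 < pos2, swapping strands along with positions.

The join class of an intrachromosomal SV is a pure function of the strand
pair under the dialect below; interchromosomal SVs always carry the
``interchromosomal`` class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

DEL_LIKE = "DEL_like"
DUP_LIKE = "DUP_like"
H2H_INV = "h2h_inv"
T2T_INV = "t2t_inv"
INTERCHROMOSOMAL = "interchromosomal"

INTRA_CLASSES = (DEL_LIKE, DUP_LIKE, H2H_INV, T2T_INV)

#: Strand-pair dialect: how BEDPE strand pairs map to fragment-join classes.
#: This matches common consensus-SV exports; it can be overridden per call.
DEFAULT_STRAND_DIALECT = {
    ("+", "-"): DEL_LIKE,
    ("-", "+"): DUP_LIKE,
    ("+", "+"): H2H_INV,
    ("-", "-"): T2T_INV,
}


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class ValidationError(ValueError):
    """Input violates a structural invariant (overlap, negative CN, ...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SV:
    """A somatic structural variant: a paired-breakpoint rearrangement.

    Positions are 1-based. For intrachromosomal SVs pos1 < pos2 and the join
    class is one of the four fragment-join types; different chromosomes imply
    the interchromosomal class.
    """

    id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    join_class: str
    homology_len: Optional[int] = None
    insertion_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise ValidationError(f"SV {self.id}: bad strand "
                                  f"({self.strand1}, {self.strand2})")
        if self.chrom1 == self.chrom2:
            if self.pos1 >= self.pos2:
                raise ValidationError(
                    f"SV {self.id}: intrachromosomal requires pos1 < pos2")
            if self.join_class == INTERCHROMOSOMAL:
                raise ValidationError(
                    f"SV {self.id}: same-chromosome SV cannot be interchromosomal")
        elif self.join_class != INTERCHROMOSOMAL:
            raise ValidationError(
                f"SV {self.id}: different chromosomes require the "
                f"interchromosomal class")

    @property
    def is_intra(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def span(self) -> Optional[int]:
        """Reference distance bridged by an intrachromosomal SV."""
        return self.pos2 - self.pos1 if self.is_intra else None


@dataclass(frozen=True)
class CNSegment:
    """Allele-specific copy-number segment; 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: start > end")
        if self.total_cn < 0:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: negative CN")
        if self.minor_cn is not None:
            if self.minor_cn < 0:
                raise ValidationError(
                    f"segment {self.chrom}:{self.start}-{self.end}: "
                    f"negative minor CN")
            if self.minor_cn > self.total_cn - self.minor_cn:
                raise ValidationError(
                    f"segment {self.chrom}:{self.start}-{self.end}: minor CN "
                    f"{self.minor_cn} exceeds major of total {self.total_cn}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SNVRecord:
    """Somatic point mutation with its reference-strand trinucleotide context."""

    chrom: str
    pos: int
    ref: str
    alt: str
    context: str
    vaf: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.context) != 3:
            raise ValidationError(
                f"SNV {self.chrom}:{self.pos}: context must be 3 bases")
        if self.context[1].upper() != self.ref.upper():
            raise ValidationError(
                f"SNV {self.chrom}:{self.pos}: context middle base "
                f"{self.context[1]} != ref {self.ref}")


@dataclass(frozen=True)
class GeneRecord:
    name: str
    chrom: str
    start: int
    end: int
    role: str = "other"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"gene {self.name}: start must be < end")


@dataclass
class SampleProfile:
    """All per-sample inputs the detector consumes."""

    sample_id: str
    svs: list[SV] = field(default_factory=list)
    cn: list[CNSegment] = field(default_factory=list)
    ploidy: float = 2.0
    purity: float = 1.0
    snvs: Optional[list[SNVRecord]] = None
    chrom_lengths: Optional[dict[str, int]] = None

    def ploidy_class(self, diploid_max: float = 2.1,
                     polyploid_min: float = 2.5) -> str:
        if self.ploidy <= diploid_max:
            return "diploid"
        if self.ploidy >= polyploid_min:
            return "polyploid"
        return "intermediate"

    def cn_by_chrom(self) -> dict[str, list[CNSegment]]:
        out: dict[str, list[CNSegment]] = {}
        for seg in self.cn:
            out.setdefault(seg.chrom, []).append(seg)
        for segs in out.values():
            segs.sort(key=lambda s: s.start)
        return out

    def chrom_length(self, chrom: str) -> int:
        """Declared chromosome length, or the extent of its CN/SV coverage."""
        if self.chrom_lengths and chrom in self.chrom_lengths:
            return self.chrom_lengths[chrom]
        ends = [s.end for s in self.cn if s.chrom == chrom]
        for sv in self.svs:
            if sv.chrom1 == chrom:
                ends.append(sv.pos1)
            if sv.chrom2 == chrom:
                ends.append(sv.pos2)
        if not ends:
            raise ValidationError(f"no data on chromosome {chrom}")
        return max(ends)


# ---------------------------------------------------------------------------
# Join-class derivation and SV construction
# ---------------------------------------------------------------------------

def join_class_from_strands(strand1: str, strand2: str,
                            dialect: Optional[dict] = None) -> str:
    """Map an intrachromosomal strand pair to its fragment-join class."""
    dialect = dialect or DEFAULT_STRAND_DIALECT
    try:
        return dialect[(strand1, strand2)]
    except KeyError:
        raise ValidationError(f"unknown strand pair ({strand1}, {strand2})")


def make_sv(id: str, chrom1: str, pos1: int, strand1: str,
            chrom2: str, pos2: int, strand2: str,
            homology_len: Optional[int] = None,
            insertion_len: Optional[int] = None,
            dialect: Optional[dict] = None) -> SV:
    """Build an SV, normalising intrachromosomal records so pos1 < pos2.

    When positions are swapped the strands travel with their breakpoints, and
    the join class is derived from the normalised strand order.
    """
    if chrom1 == chrom2 and pos1 > pos2:
        pos1, pos2 = pos2, pos1
        strand1, strand2 = strand2, strand1
    if chrom1 == chrom2:
        jc = join_class_from_strands(strand1, strand2, dialect)
    else:
        jc = INTERCHROMOSOMAL
    return SV(id=id, chrom1=chrom1, pos1=pos1, strand1=strand1,
              chrom2=chrom2, pos2=pos2, strand2=strand2, join_class=jc,
              homology_len=homology_len, insertion_len=insertion_len)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_sv_bedpe(path: str | Path,
                  dialect: Optional[dict] = None) -> list[SV]:
    """Read a BEDPE file (0-based half-open) into internal SV records.

    Columns: chrom1 start1 end1 chrom2 start2 end2 [name [score]] strand1
    strand2 [homlen [insertion]]. A header line starting with '#' or
    'chrom1' is skipped. Each breakpoint is collapsed to the end coordinate
    of its interval (1-based position of its last base).
    """
    svs: list[SV] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "chrom1":
                continue
            if len(parts) < 10:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 10 BEDPE columns, "
                    f"got {len(parts)}")
            try:
                chrom1, chrom2 = parts[0], parts[3]
                start1, start2 = int(parts[1]), int(parts[4])
                end1, end2 = int(parts[2]), int(parts[5])
                if start1 >= end1 or start2 >= end2:
                    raise ValueError("empty breakpoint interval")
                name = parts[6] or f"sv{lineno}"
                strand1, strand2 = parts[8], parts[9]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if strand1 not in "+-" or strand2 not in "+-":
                raise ParseError(
                    f"{path}:{lineno}: unknown strand symbol "
                    f"({strand1!r}, {strand2!r})")

            def _opt(idx: int) -> Optional[int]:
                if len(parts) > idx and parts[idx] not in ("", ".", "NA"):
                    return int(parts[idx])
                return None

            try:
                hom, ins = _opt(10), _opt(11)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                svs.append(make_sv(name, chrom1, end1, strand1,
                                   chrom2, end2, strand2,
                                   homology_len=hom, insertion_len=ins,
                                   dialect=dialect))
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return svs


def write_sv_bedpe(svs: Sequence[SV], path: str | Path) -> None:
    """Write SVs as 10+2 column BEDPE (inverse of :func:`read_sv_bedpe`)."""
    with open(path, "w") as fh:
        fh.write("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\t"
                 "name\tscore\tstrand1\tstrand2\thomlen\tinsertion\n")
        for sv in svs:
            hom = "." if sv.homology_len is None else str(sv.homology_len)
            ins = "." if sv.insertion_len is None else str(sv.insertion_len)
            fh.write(f"{sv.chrom1}\t{sv.pos1 - 1}\t{sv.pos1}\t"
                     f"{sv.chrom2}\t{sv.pos2 - 1}\t{sv.pos2}\t"
                     f"{sv.id}\t.\t{sv.strand1}\t{sv.strand2}\t{hom}\t{ins}\n")


def merge_equal_neighbors(segments: Sequence[CNSegment]) -> list[CNSegment]:
    """Merge adjacent same-chromosome segments with identical CN state.

    Oscillation counting is defined on state changes, so duplicated states
    must be collapsed; the operation is idempotent.
    """
    by_chrom: dict[str, list[CNSegment]] = {}
    order: list[str] = []
    for seg in segments:
        if seg.chrom not in by_chrom:
            order.append(seg.chrom)
        by_chrom.setdefault(seg.chrom, []).append(seg)
    out: list[CNSegment] = []
    for chrom in order:
        segs = sorted(by_chrom[chrom], key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start <= prev.end:
                raise ValidationError(
                    f"overlapping segments on {chrom}: "
                    f"{prev.start}-{prev.end} and {cur.start}-{cur.end}")
        merged = [segs[0]]
        for cur in segs[1:]:
            prev = merged[-1]
            if (cur.total_cn == prev.total_cn
                    and cur.minor_cn == prev.minor_cn):
                merged[-1] = replace(prev, end=cur.end)
            else:
                merged.append(cur)
        out.extend(merged)
    return out


def read_cn_segments(path: str | Path) -> list[CNSegment]:
    """Read a seg TSV (chrom/start/end/total_cn[/minor_cn]), validate, merge.

    Segments are sorted per chromosome, overlaps are rejected, and adjacent
    segments with identical (total_cn, minor_cn) are merged.
    """
    segs: list[CNSegment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = [h.strip().lower() for h in header]
        required = ("chrom", "start", "end", "total_cn")
        if cols[:4] != list(required):
            raise ParseError(
                f"{path}:1: header must begin {'/'.join(required)}")
        has_minor = len(cols) > 4 and cols[4] == "minor_cn"
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                minor = None
                if has_minor and len(parts) > 4 and parts[4] not in ("", ".", "NA"):
                    minor = int(parts[4])
                segs.append(CNSegment(chrom=parts[0], start=int(parts[1]),
                                      end=int(parts[2]),
                                      total_cn=int(parts[3]),
                                      minor_cn=minor))
            except (ValueError, IndexError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return merge_equal_neighbors(segs)


def write_cn_segments(segments: Sequence[CNSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\ttotal_cn\tminor_cn\n")
        for s in segments:
            minor = "." if s.minor_cn is None else str(s.minor_cn)
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.total_cn}\t{minor}\n")


def read_snv_table(path: str | Path) -> list[SNVRecord]:
    """Read an SNV TSV with columns chrom/pos/ref/alt/context[/vaf]."""
    out: list[SNVRecord] = []
    with open(path) as fh:
        header = [h.strip().lower() for h in fh.readline().rstrip("\n").split("\t")]
        idx = {name: i for i, name in enumerate(header)}
        for need in ("chrom", "pos", "ref", "alt", "context"):
            if need not in idx:
                raise ParseError(f"{path}:1: missing column {need!r}")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                vaf = None
                if "vaf" in idx and len(parts) > idx["vaf"]:
                    v = parts[idx["vaf"]]
                    vaf = float(v) if v not in ("", ".", "NA") else None
                out.append(SNVRecord(chrom=parts[idx["chrom"]],
                                     pos=int(parts[idx["pos"]]),
                                     ref=parts[idx["ref"]],
                                     alt=parts[idx["alt"]],
                                     context=parts[idx["context"]],
                                     vaf=vaf))
            except (ValueError, IndexError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_snv_table(snvs: Sequence[SNVRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tcontext\tvaf\n")
        for s in snvs:
            vaf = "." if s.vaf is None else f"{s.vaf:.4f}"
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.context}\t{vaf}\n")


def read_genes_bed(path: str | Path) -> list[GeneRecord]:
    """Read a gene BED (chrom start end name [score [strand [role]]])."""
    out: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected >= 4 BED columns")
            role = parts[6] if len(parts) > 6 else "other"
            try:
                out.append(GeneRecord(name=parts[3], chrom=parts[0],
                                      start=int(parts[1]) + 1,
                                      end=int(parts[2]), role=role))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_metadata(path: str | Path) -> dict[str, dict]:
    """Read a metadata TSV (sample_id/ploidy/purity) keyed by sample."""
    out: dict[str, dict] = {}
    with open(path) as fh:
        header = [h.strip().lower() for h in fh.readline().rstrip("\n").split("\t")]
        idx = {name: i for i, name in enumerate(header)}
        for need in ("sample_id", "ploidy", "purity"):
            if need not in idx:
                raise ParseError(f"{path}:1: missing column {need!r}")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                out[parts[idx["sample_id"]]] = {
                    "ploidy": float(parts[idx["ploidy"]]),
                    "purity": float(parts[idx["purity"]]),
                }
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Call output
# ---------------------------------------------------------------------------

CALL_TSV_COLUMNS = [
    "sample_id", "event_id", "chrom", "region_start", "region_end",
    "n_intra", "n_inter", "n_del", "n_dup", "n_h2h", "n_t2t",
    "max_osc_2", "max_osc_3", "frac_osc_2",
    "p_fragment_joins", "p_exponential", "p_enrichment",
    "loh_interspersed", "foldback_fraction",
    "median_homology", "frac_long_homology",
    "confidence", "canonical", "double_minute_candidate", "rejected_reason",
]


def write_calls(calls: Sequence, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write calls as a per-(event, chromosome) TSV plus a full JSON twin.

    ``path_prefix`` gains ``.tsv`` and ``.json`` suffixes. The JSON twin
    round-trips through :func:`read_calls` to identical call objects.
    """
    prefix = Path(path_prefix)
    tsv_path = prefix.with_suffix(".tsv")
    json_path = prefix.with_suffix(".json")

    def fmt(v) -> str:
        if v is None:
            return "NA"
        if isinstance(v, bool):
            return str(v)
        if isinstance(v, float):
            return f"{v:.6g}"
        return str(v)

    with open(tsv_path, "w") as fh:
        fh.write("\t".join(CALL_TSV_COLUMNS) + "\n")
        for call in calls:
            for row in call.tsv_rows():
                fh.write("\t".join(fmt(row[c]) for c in CALL_TSV_COLUMNS) + "\n")
    with open(json_path, "w") as fh:
        json.dump([call.to_dict() for call in calls], fh, indent=1, sort_keys=True)
        fh.write("\n")
    return tsv_path, json_path


def read_calls(json_path: str | Path) -> list:
    """Read back the JSON twin written by :func:`write_calls`."""
    from .caller import ChromothripsisCall  # deferred: caller imports this module
    with open(json_path) as fh:
        data = json.load(fh)
    return [ChromothripsisCall.from_dict(d) for d in data]
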