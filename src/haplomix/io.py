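"""Readers and writers bridging standard formats to the domain types.

Coordinates are 1-based inclusive internally; conversions happen only at
the SAM boundary (0-based alignment start) and the BED boundary (0-based
half-open).  SAM/BAM ingest walks the CIGAR of each mapped record to a
per-reference-position state vector (M/X/= emit the query base, D emits
'-', I attaches an insertion to the preceding gap, S/H are clipped);
unmapped, secondary and supplementary records are dropped and counted.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .metrics import VariantRecord
from .model import (
    GAP,
    AlignedRead,
    ConsensusHaplotype,
    ModelError,
    ReferenceSequence,
)

__all__ = [
    "FormatError",
    "IngestReport",
    "read_reference",
    "load_aligned_reads",
    "write_haplotypes",
    "read_haplotype_table",
    "write_vcf",
    "write_reads_fasta",
    "write_sam",
    "write_truth_table",
    "write_assignments",
    "write_fit_report",
    "read_site_list",
    "parse_region",
]


class FormatError(ValueError):
    pass


@dataclass
class IngestReport:
    n_total: int = 0
    n_kept: int = 0
    n_dropped_unmapped: int = 0
    n_dropped_secondary: int = 0
    n_dropped_filters: int = 0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        pass

    @property
    def consistent(self) -> bool:
        return self.n_total == (self.n_kept + self.n_dropped_unmapped
                                + self.n_dropped_secondary
                                + self.n_dropped_filters)


def read_reference(path, contig: str | None = None) -> ReferenceSequence:
    """Load a reference contig from FASTA (first record, or ``contig`` by
    name), uppercased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    if contig is None:
        rec = records[0]
    else:
        by_name = {r.id: r for r in records}
        if contig not in by_name:
            raise FormatError(f"{path}: contig {contig!r} not found "
                              f"(available: {', '.join(by_name)})")
        rec = by_name[contig]
    return ReferenceSequence(name=rec.id, bases=str(rec.seq).upper())


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse 'contig:start-end' (1-based inclusive)."""
    m = re.fullmatch(r"([^:]+):(\d+)-(\d+)", region)
    if not m:
        raise FormatError(f"bad region {region!r}; expected contig:start-end")
    contig, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start < 1 or end < start:
        raise FormatError(f"bad region bounds in {region!r}")
    return contig, start, end


def _record_to_read(rec: pysam.AlignedSegment) -> AlignedRead:
    seq = rec.query_sequence
    if seq is None:
        raise FormatError("record has no sequence")
    states: list[str] = []
    insertions: dict[int, str] = {}
    ref_pos = rec.reference_start  # 0-based
    q = 0
    for op, ln in rec.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            states.append(seq[q:q + ln].upper())
            q += ln
            ref_pos += ln
        elif op == 2:  # D
            states.append(GAP * ln)
            ref_pos += ln
        elif op == 1:  # I: gap between 1-based positions ref_pos and ref_pos+1
            g = ref_pos
            if g > rec.reference_start:  # leading insertions have no gap
                insertions[g] = insertions.get(g, "") + seq[q:q + ln].upper()
            q += ln
        elif op == 4:  # S
            q += ln
        elif op in (5, 6):  # H, P
            pass
        elif op == 3:  # N
            raise FormatError("N (skipped region) CIGAR op unsupported")
        else:
            raise FormatError(f"unsupported CIGAR op {op}")
    start = rec.reference_start + 1
    end = rec.reference_end  # pysam: 1-past-last 0-based == 1-based inclusive
    insertions = {g: s for g, s in insertions.items() if start <= g <= end - 1}
    return AlignedRead(name=rec.query_name, start=start, end=end,
                       states="".join(states), insertions=insertions)


def _clip_read(read: AlignedRead, lo: int, hi: int) -> AlignedRead | None:
    """Clip a read to region [lo, hi]; None when nothing informative is left."""
    s = max(read.start, lo)
    e = min(read.end, hi)
    if e < s:
        return None
    states = read.states[s - read.start:e - read.start + 1]
    if not states or set(states) <= {GAP}:
        return None
    # an alignment must start/end on an observed base
    first = len(states) - len(states.lstrip(GAP))
    last = len(states.rstrip(GAP))
    s2, e2 = s + first, s + last - 1
    states = states[first:last]
    ins = {g: v for g, v in read.insertions.items() if s2 <= g <= e2 - 1}
    return AlignedRead(name=read.name, start=s2, end=e2, states=states,
                       insertions=ins, truth_source=read.truth_source)


def load_aligned_reads(
    path, reference: ReferenceSequence, region: str | None = None
) -> tuple[list[AlignedRead], IngestReport]:
    """Load mapped records from SAM/BAM as :class:`AlignedRead` objects.

    Records mapped to ``reference.name`` (or the region's contig) are kept;
    unmapped, secondary and supplementary records are dropped and counted;
    malformed records are skipped with a warning.  ``region`` restricts and
    clips to 'contig:start-end'.
    """
    report = IngestReport()
    lo, hi = 1, reference.length
    contig = reference.name
    if region is not None:
        contig, lo, hi = parse_region(region)
    reads: list[AlignedRead] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        contigs = set(af.references or ())
        if contigs and contig not in contigs:
            raise FormatError(f"contig {contig!r} absent from {path}")
        for rec in af.fetch(until_eof=True):
            report.n_total += 1
            if rec.is_unmapped:
                report.n_dropped_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                report.n_dropped_secondary += 1
                continue
            if rec.reference_name != contig:
                report.n_dropped_filters += 1
                continue
            try:
                read = _record_to_read(rec)
            except (FormatError, ModelError) as exc:
                report.n_dropped_filters += 1
                report.warnings.append(f"{rec.query_name}: {exc}")
                continue
            if read.end > reference.length:
                report.n_dropped_filters += 1
                report.warnings.append(
                    f"{rec.query_name}: alignment beyond reference end")
                continue
            if region is not None:
                clipped = _clip_read(read, lo, hi)
                if clipped is None:
                    report.n_dropped_filters += 1
                    continue
                read = clipped
            reads.append(read)
            report.n_kept += 1
    for msg in report.warnings:
        warnings.warn(msg, stacklevel=2)
    return reads, report


# ---------------------------------------------------------------------------
# haplotype output
# ---------------------------------------------------------------------------


def write_haplotypes(haps: Sequence[ConsensusHaplotype], fasta_path,
                     table_path=None) -> None:
    """Write haplotypes as FASTA (literal sequences: '-' removed, insertions
    spliced in) plus an optional per-position TSV preserving the
    reference-indexed representation (lossless round trip)."""
    records = [SeqRecord(Seq(h.literal_sequence()), id=f"haplotype_{h.index}",
                         description="") for h in haps]
    SeqIO.write(records, str(fasta_path), "fasta")
    if table_path is None:
        return
    rows = []
    for h in haps:
        for pos, s in enumerate(h.states, start=1):
            rows.append((h.index, "position", pos, s))
        for g in sorted(h.insertions):
            rows.append((h.index, "gap", g, h.insertions[g]))
    pd.DataFrame(rows, columns=["haplotype", "kind", "index", "value"]) \
        .to_csv(table_path, sep="\t", index=False)


def read_haplotype_table(path) -> list[ConsensusHaplotype]:
    df = pd.read_csv(path, sep="\t", dtype={"value": str})
    haps = []
    for k, sub in df.groupby("haplotype"):
        pos = sub[sub["kind"] == "position"].sort_values("index")
        states = "".join(pos["value"].tolist())
        ins = {int(r["index"]): str(r["value"])
               for _, r in sub[sub["kind"] == "gap"].iterrows()}
        haps.append(ConsensusHaplotype(index=int(k), states=states,
                                       insertions=ins))
    return haps


def write_vcf(variants: Sequence[VariantRecord],
              reference: ReferenceSequence, path) -> None:
    """Write substitution calls as VCF 4.2 with one polyploid sample whose
    genotype lists each haplotype's allele index (0 = reference)."""
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    header.add_line(f'##contig=<ID={reference.name},length={reference.length}>')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,'
                    'Description="Per-haplotype allele indices">')
    header.add_sample("haplotypes")
    snvs = sorted((v for v in variants if v.is_snv), key=lambda v: v.position)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in snvs:
            alleles = [v.ref, *v.alts]
            rec = vf.new_record(contig=reference.name, start=v.position - 1,
                                stop=v.position, alleles=alleles)
            idx = tuple(alleles.index(a) if a in alleles else None
                        for a in v.alleles)
            rec.samples["haplotypes"]["GT"] = idx
            vf.write(rec)


# ---------------------------------------------------------------------------
# simulated-dataset output
# ---------------------------------------------------------------------------


def write_reads_fasta(reads: Sequence[AlignedRead], path) -> None:
    """Reads as literal sequences ('-' removed, insertions spliced in)."""
    records = []
    for r in reads:
        parts = []
        for off, s in enumerate(r.states):
            if s != GAP:
                parts.append(s)
            g = r.start + off
            if g in r.insertions:
                parts.append(r.insertions[g])
        records.append(SeqRecord(Seq("".join(parts)), id=r.name,
                                 description=""))
    SeqIO.write(records, str(path), "fasta")


def _read_to_cigar(read: AlignedRead) -> tuple[str, str]:
    """Rebuild (sequence, CIGAR) from the per-position representation."""
    ops: list[tuple[str, int]] = []
    seq_parts: list[str] = []

    def push(op: str, ln: int) -> None:
        if ln == 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + ln)
        else:
            ops.append((op, ln))

    for off, s in enumerate(read.states):
        if s == GAP:
            push("D", 1)
        else:
            push("M", 1)
            seq_parts.append(s)
        g = read.start + off
        if g in read.insertions and off < len(read.states) - 1:
            ins = read.insertions[g]
            push("I", len(ins))
            seq_parts.append(ins)
    cigar = "".join(f"{ln}{op}" for op, ln in ops)
    return "".join(seq_parts), cigar


def write_sam(reads: Sequence[AlignedRead], reference: ReferenceSequence,
              path) -> None:
    """Write reads as an aligned SAM with true-source tags (HP) when known."""
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": reference.name, "LN": reference.length}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as af:
        for r in reads:
            seq, cigar = _read_to_cigar(r)
            a = pysam.AlignedSegment(af.header)
            a.query_name = r.name
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = 0
            a.reference_start = r.start - 1
            a.mapping_quality = 60
            a.cigarstring = cigar
            if r.truth_source is not None:
                a.set_tag("HP", int(r.truth_source))
            af.write(a)


def write_truth_table(reads: Sequence[AlignedRead], path) -> None:
    pd.DataFrame(
        [(r.name, r.truth_source, r.start, r.end) for r in reads],
        columns=["read", "haplotype", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


def write_assignments(reads: Sequence[AlignedRead], labels,
                      responsibilities, path) -> None:
    resp = np.asarray(responsibilities)
    labels = np.asarray(labels, dtype=int)
    pd.DataFrame({
        "read": [r.name for r in reads],
        "haplotype": labels + 1,
        "responsibility": resp[np.arange(len(labels)), labels],
    }).to_csv(path, sep="\t", index=False)


def write_fit_report(report: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=default))


def read_site_list(path) -> list[int]:
    """Read a site list: 1-based two-column TSV (contig, pos) or BED
    (0-based half-open), auto-detected by extension."""
    path = Path(path)
    sites: list[int] = []
    if path.suffix.lower() == ".bed":
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            start, end = int(parts[1]), int(parts[2])
            sites.extend(range(start + 1, end + 1))
    else:
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            sites.append(int(parts[1] if len(parts) > 1 else parts[0]))
    return sorted(set(sites))
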