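"""File formats: FASTA references, SAM/TSV read alignments, count tables.

All output tables are tab-separated with a single header line; runs may
prepend '#'-prefixed provenance comments (tool version, timestamp, full
parameter echo) which every reader here skips.

The aligned-read fixture format is a four-column TSV — read_id,
ref_start (1-based), bases, phred+33 quality string — equivalent in
content to a substitution-only SAM record and convenient for hand-built
test fixtures.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .interactome import MissingBaitError, SpectralCountTable
from .refseq import CodingSequence
from .screen import AlignedRead

__all__ = [
    "read_fasta",
    "read_alignments",
    "read_sam",
    "read_reads_tsv",
    "write_reads_tsv",
    "write_sam",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_table_tsv",
    "provenance",
]

log = logging.getLogger("actmap")

_SAMPLE_COL = re.compile(r"^(?P<cond>.+)_rep(?P<rep>\d+)$")


def read_fasta(path, ref_id: str | None = None) -> CodingSequence:
    """Read a coding sequence from FASTA (frame-validated).

    The first record is used unless ``ref_id`` names another; a warning
    is logged when a multi-record file is read without an explicit id.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if ref_id is None:
        if len(records) > 1:
            log.warning(
                "%s has %d records; using the first (%s)",
                path, len(records), records[0].id,
            )
        record = records[0]
    else:
        matches = [r for r in records if r.id == ref_id]
        if not matches:
            raise ValueError(f"record {ref_id!r} not found in {path}")
        record = matches[0]
    return CodingSequence(id=record.id, nt=str(record.seq).upper())


def quals_from_phred33(qstring: str) -> np.ndarray:
    return np.array([ord(c) - 33 for c in qstring], dtype=np.int16)


def quals_to_phred33(quals) -> str:
    return "".join(chr(int(q) + 33) for q in quals)


def read_reads_tsv(path) -> list:
    """Read the aligned-read TSV fixture format."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "read_id":  # header
                continue
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            read_id, ref_start, bases, quals = fields
            reads.append(
                AlignedRead(
                    read_id=read_id,
                    ref_start=int(ref_start),
                    bases=bases,
                    quals=quals_from_phred33(quals),
                )
            )
    return reads


def write_reads_tsv(reads, path, provenance_block: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in _provenance_lines(provenance_block):
            fh.write(line)
        fh.write("read_id\tref_start\tbases\tquals\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.ref_start}\t{r.bases}\t"
                f"{quals_to_phred33(r.quals)}\n"
            )


_PURE_MATCH_OPS = {0, 7, 8}  # M, =, X


def read_sam(path, cds: CodingSequence) -> list:
    """Read mapped primary alignments from SAM against one reference.

    Unmapped, secondary and supplementary records are skipped (with
    logged tallies); records whose CIGAR contains insertions, deletions
    or clipping are kept but flagged ``indel_or_clip`` so the screen QC
    can count them. Reverse-strand records arrive in SAM already
    reverse-complemented to reference orientation, which is what the
    strand-agnostic coding-sequence analysis needs.
    """
    reads = []
    skipped = {"unmapped": 0, "secondary": 0, "supplementary": 0}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        if sam.header.get("SQ"):
            sq = sam.header["SQ"][0]
            if sq.get("SN") != cds.id or sq.get("LN") != len(cds.nt):
                raise ValueError(
                    f"SAM reference {sq.get('SN')!r}/{sq.get('LN')} does not "
                    f"match {cds.id!r}/{len(cds.nt)}"
                )
        for rec in sam:
            if rec.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if rec.is_secondary:
                skipped["secondary"] += 1
                continue
            if rec.is_supplementary:
                skipped["supplementary"] += 1
                continue
            cig = rec.cigartuples or []
            pure = all(op in _PURE_MATCH_OPS for op, _ in cig)
            quals = rec.query_qualities
            if quals is None:
                quals = np.full(len(rec.query_sequence), 40, dtype=np.int16)
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    ref_start=rec.reference_start + 1,
                    bases=rec.query_sequence.upper(),
                    quals=np.asarray(quals, dtype=np.int16),
                    indel_or_clip=not pure,
                )
            )
    if any(skipped.values()):
        log.info("skipped SAM records: %s", skipped)
    return reads


def write_sam(reads, path, cds: CodingSequence) -> None:
    """Write substitution-only alignments as plain-text SAM."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{cds.id}\tLN:{len(cds.nt)}\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t0\t{cds.id}\t{r.ref_start}\t60\t"
                f"{len(r.bases)}M\t*\t0\t0\t{r.bases}\t"
                f"{quals_to_phred33(r.quals)}\n"
            )


def read_alignments(path, cds: CodingSequence) -> list:
    """Dispatch on extension: ``.sam`` via pysam, otherwise the TSV fixture."""
    if str(path).endswith(".sam"):
        return read_sam(path, cds)
    return read_reads_tsv(path)


def read_counts_tsv(
    path,
    bait_id: str,
    cond_a: str | None = None,
    cond_b: str | None = None,
) -> SpectralCountTable:
    """Read a spectral-count TSV into a combined-isoform table.

    Expected columns: ``protein_group_id``, ``isoform_lengths``
    (semicolon-separated amino-acid lengths), then one count column per
    sample named ``<condition>_rep<k>``. Rows sharing a protein group id
    are isoform rows: their counts are summed and their lengths pooled,
    the normalising length being the mean over all isoforms. This is the
    layout a two-condition spreadsheet export converts to.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_group_id": str})
    required = {"protein_group_id", "isoform_lengths"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    sample_cols = []
    conditions = []
    for col in df.columns:
        m = _SAMPLE_COL.match(col)
        if m:
            sample_cols.append((col, m.group("cond"), int(m.group("rep"))))
            if m.group("cond") not in conditions:
                conditions.append(m.group("cond"))
    if len(conditions) != 2:
        raise ValueError(
            f"{path}: need exactly two conditions in sample columns, "
            f"found {conditions}"
        )
    if cond_a is not None and cond_b is not None:
        if {cond_a, cond_b} != set(conditions):
            raise ValueError(
                f"requested conditions ({cond_a}, {cond_b}) not in file "
                f"({conditions})"
            )
        conditions = [cond_a, cond_b]
    for col, _, _ in sample_cols:
        if (pd.to_numeric(df[col], errors="raise") < 0).any():
            raise ValueError(f"{path}: negative count in column {col}")

    lengths: dict[str, list] = {}
    counts: dict[str, np.ndarray] = {}
    order = []
    ncols = len(sample_cols)
    for _, row in df.iterrows():
        pid = row["protein_group_id"]
        iso = [float(x) for x in str(row["isoform_lengths"]).split(";") if x != ""]
        if not iso or any(x <= 0 for x in iso):
            raise ValueError(f"{path}: invalid isoform_lengths for {pid!r}")
        vec = np.array([float(row[c]) for c, _, _ in sample_cols])
        if pid not in counts:
            counts[pid] = np.zeros(ncols)
            lengths[pid] = []
            order.append(pid)
        counts[pid] += vec
        lengths[pid].extend(iso)

    col_index = pd.MultiIndex.from_tuples(
        [(cond, rep) for _, cond, rep in sample_cols]
    )
    count_df = pd.DataFrame(
        [counts[p] for p in order], index=order, columns=col_index
    )
    length_series = pd.Series(
        {p: float(np.mean(lengths[p])) for p in order}
    ).reindex(order)
    if bait_id not in count_df.index:
        raise MissingBaitError(f"bait {bait_id!r} not present in {path}")
    log.info(
        "read %d protein groups (%d isoform rows) from %s",
        len(order), len(df), path,
    )
    return SpectralCountTable(
        counts=count_df,
        lengths=length_series,
        bait_id=bait_id,
        conditions=tuple(conditions),
    )


def write_counts_tsv(
    table: SpectralCountTable, path, provenance_block: dict | None = None
) -> None:
    """Write a SpectralCountTable in the layout read_counts_tsv expects."""
    cols = list(table.counts.columns)
    with open(path, "w") as fh:
        for line in _provenance_lines(provenance_block):
            fh.write(line)
        header = ["protein_group_id", "isoform_lengths"] + [
            f"{cond}_rep{rep}" for cond, rep in cols
        ]
        fh.write("\t".join(header) + "\n")
        for pid in table.counts.index:
            row = [pid, f"{table.lengths[pid]:g}"] + [
                f"{table.counts.loc[pid, c]:g}" for c in cols
            ]
            fh.write("\t".join(row) + "\n")


def provenance(**params) -> dict:
    """Provenance block embedded as '#' comments in analysis outputs."""
    from . import __version__

    return {
        "tool": f"actmap {__version__}",
        "timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
        **params,
    }


def _provenance_lines(block: dict | None) -> list:
    if not block:
        return []
    return [f"# {k} = {v}\n" for k, v in block.items()]


def write_table_tsv(
    df: pd.DataFrame, path, provenance_block: dict | None = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in _provenance_lines(provenance_block):
            fh.write(line)
        df.to_csv(fh, sep="\t", index=False)
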