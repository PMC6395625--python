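"""Format plumbing: FASTQ/FASTA via Biopython, SAM via pysam, BLAST tabular
and TSV via pandas, plus minimal single-sample VCF emission.

Coordinate conventions: everything in memory is 0-based half-open; VCF output
is 1-based with anchor bases on indels, TSV outputs stay 0-based (column names
say so)."""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import AlignedRead
from .edits import DEL, INS, SUB
from .select import Read, VariantCall, calls_from_cigar
from .validation import Verdict

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# --------------------------------------------------------------------- FASTQ


def read_fastq(path) -> list[Read]:
    return [
        Read(rec.id, str(rec.seq), np.array(rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Iterable[Read], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.quals]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: "dict[str, str] | Iterable[Read]", path) -> None:
    if isinstance(seqs, dict):
        records = [SeqRecord(Seq(s), id=n, description="") for n, s in seqs.items()]
    else:
        records = [SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in seqs]
    SeqIO.write(records, str(path), "fasta")


# ----------------------------------------------------------------------- SAM


def read_sam_alignments(path, reference: str) -> list[tuple[Read, AlignedRead]]:
    """Ingest per-read alignments from a SAM file.

    CIGAR ``M`` operations are split into ``=``/``X`` by comparing the query
    to the given reference, so files written with either convention parse to
    the same edit path.  Unmapped and secondary records are skipped; soft
    clips are stripped from the returned read (only the aligned portion is
    kept).
    """
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.query_alignment_sequence
            if seq is None:
                continue
            quals = (
                np.array(rec.query_alignment_qualities)
                if rec.query_alignment_qualities is not None
                else np.zeros(len(seq), dtype=np.int16)
            )
            cigar = []
            i, j = 0, rec.reference_start
            for op, n in rec.cigartuples or ():
                code = "MIDNSHP=XB"[op]
                if code == "M":
                    for t in range(n):
                        c = "=" if seq[i + t] == reference[j + t] else "X"
                        if cigar and cigar[-1][0] == c:
                            cigar[-1][1] += 1
                        else:
                            cigar.append([c, 1])
                    i += n
                    j += n
                elif code in "=X":
                    cigar.append([code, n])
                    i += n
                    j += n
                elif code == "I":
                    cigar.append(["I", n])
                    i += n
                elif code == "D":
                    cigar.append(["D", n])
                    j += n
                elif code in "SH":
                    pass  # clipped bases already excluded from seq
                else:
                    raise ValueError(f"unsupported CIGAR op {code!r} in {rec.query_name}")
            strand = "-" if rec.is_reverse else "+"
            aln = AlignedRead(
                rec.query_name, rec.reference_start, j,
                tuple((c, n) for c, n in cigar), strand,
            )
            out.append((Read(rec.query_name, seq, quals), aln))
    return out


# ------------------------------------------------------------- BLAST tabular


def read_blast_tabular(path) -> pd.DataFrame:
    """12-column BLAST outfmt-6 table."""
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    if df.shape[1] != len(BLAST6_COLUMNS):
        raise ValueError(
            f"expected {len(BLAST6_COLUMNS)} BLAST tabular columns, got {df.shape[1]}"
        )
    df.columns = BLAST6_COLUMNS
    return df


def alignments_from_blast(
    table: pd.DataFrame, reads: Sequence[Read], reference: str, band_width: int = 16
) -> dict[str, AlignedRead]:
    """Re-derive edit paths for BLAST tabular hits by realignment.

    The 12-column format has no per-base edit trace, so each hit's query is
    realigned with the internal banded aligner; the table only decides which
    reads count as aligned.
    """
    from .alignment import align_read

    by_id = {r.read_id: r for r in reads}
    out = {}
    for qseqid in table["qseqid"].unique():
        read = by_id.get(str(qseqid))
        if read is None:
            raise KeyError(f"BLAST hit for unknown read {qseqid!r}")
        out[read.read_id] = align_read(
            read.sequence, reference, band_width, read_id=read.read_id
        )
    return out


# ----------------------------------------------------------------- TSV / VCF


def calls_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": c.read_id, "pos0": c.pos, "kind": c.kind,
                "ref": c.ref, "alt": c.alt, "in_primer": c.in_primer,
            }
            for c in calls
        ],
        columns=["read_id", "pos0", "kind", "ref", "alt", "in_primer"],
    )


def write_calls_tsv(calls: Sequence[VariantCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> list[VariantCall]:
    df = pd.read_csv(str(path), sep="\t", keep_default_na=False)
    return [
        VariantCall(
            str(r.read_id), int(r.pos0), str(r.kind), str(r.ref), str(r.alt),
            bool(r.in_primer),
        )
        for r in df.itertuples()
    ]


def _vcf_record(pos: int, kind: str, ref: str, alt: str, reference: str):
    """1-based VCF coordinates with anchor bases for indels."""
    if kind == SUB:
        return pos + 1, ref, alt
    if kind == INS:
        if pos == 0:
            return 1, reference[0], alt + reference[0]
        anchor = reference[pos - 1]
        return pos, anchor, anchor + alt
    if kind == DEL:
        if pos == 0:
            after = reference[len(ref)]
            return 1, ref + after, after
        anchor = reference[pos - 1]
        return pos, anchor + ref, anchor
    raise ValueError(f"unknown kind {kind!r}")


def write_vcf(
    calls: Sequence[VariantCall],
    reference: str,
    path,
    verdicts: Sequence[Verdict] | None = None,
    contig: str = "amplicon",
) -> None:
    """Minimal single-sample VCF (4.2) of per-read variant calls, aggregated
    per allele with read-support counts; verdicts, when given, are carried in
    INFO ``VALIDATION=``."""
    verdict_of = {}
    for v in verdicts or ():
        key = v.variant.allele_key()
        verdict_of[key] = {
            "artifact": "artifact",
            "true_variant": "true",
            "validation_artifact": "validation_artifact",
            "indeterminate": "indeterminate",
        }[v.category]
    support: dict[tuple, int] = {}
    meta: dict[tuple, VariantCall] = {}
    for c in calls:
        key = c.allele_key()
        support[key] = support.get(key, 0) + 1
        meta.setdefault(key, c)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={len(reference)}>",
        '##INFO=<ID=RS,Number=1,Type=Integer,Description="Supporting read count">',
        '##INFO=<ID=VALIDATION,Number=1,Type=String,'
        'Description="Clone validation verdict: artifact|true|validation_artifact|indeterminate">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for key in sorted(support):
        c = meta[key]
        pos1, ref, alt = _vcf_record(c.pos, c.kind, c.ref, c.alt, reference)
        info = f"RS={support[key]}"
        if key in verdict_of:
            info += f";VALIDATION={verdict_of[key]}"
        lines.append(f"{contig}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_verdicts_tsv(verdicts: Sequence[Verdict], path) -> None:
    pd.DataFrame(
        [
            {
                "read_id": v.variant.read_id, "pos0": v.variant.pos,
                "kind": v.variant.kind, "ref": v.variant.ref, "alt": v.variant.alt,
                "in_primer": v.variant.in_primer, "category": v.category,
                "consensus_fraction": v.consensus_fraction, "usable": v.usable,
            }
            for v in verdicts
        ]
    ).to_csv(path, sep="\t", index=False)


def read_layout_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t")
    required = {"read_id", "pixel_x", "pixel_y"}
    if not required <= set(df.columns):
        raise ValueError(f"layout table must have columns {sorted(required)}")
    return df


# -------------------------------------------------------------------- frames


def write_frames_tiff(frames: dict, outdir) -> list[str]:
    """Write rendered chip frames as 16-bit grayscale TIFF tiles."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame_id, img in frames.items():
        arr = np.asarray(img, dtype=np.float64)
        top = arr.max() if arr.max() > 0 else 1.0
        u16 = np.clip(arr / top * 65535.0, 0, 65535).astype(np.uint16)
        name = "frame_" + "_".join(str(k) for k in np.atleast_1d(frame_id)) + ".tiff"
        path = outdir / name
        tifffile.imwrite(path, u16)
        paths.append(str(path))
    return paths


def read_frame_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path)).astype(np.float64)


# --------------------------------------------------------------- conversion


def convert(path_in, format_in: str, path_out, format_out: str, reference: str | None = None) -> None:
    """Lossless-where-representable conversion between supported formats.

    Supported pairs: fastq->fasta (drops qualities, keeps ids and order),
    calls_tsv->vcf (0-based TSV to 1-based anchored VCF; needs ``reference``),
    sam->calls_tsv (per-read variant calls from SAM edit paths; needs
    ``reference``).
    """
    pair = (format_in.lower(), format_out.lower())
    if pair == ("fastq", "fasta"):
        records = list(SeqIO.parse(str(path_in), "fastq"))
        SeqIO.write(records, str(path_out), "fasta")
    elif pair == ("calls_tsv", "vcf"):
        if reference is None:
            raise ValueError("calls_tsv -> vcf conversion needs the reference sequence")
        write_vcf(read_calls_tsv(path_in), reference, path_out)
    elif pair == ("sam", "calls_tsv"):
        if reference is None:
            raise ValueError("sam -> calls_tsv conversion needs the reference sequence")
        from .edits import normalize_edit
        from dataclasses import replace as _replace

        calls: list[VariantCall] = []
        for read, aln in read_sam_alignments(path_in, reference):
            sub_ref = reference[aln.ref_start : aln.ref_end]
            for e in calls_from_cigar(aln.cigar, read.sequence, sub_ref):
                e = normalize_edit(reference, _replace(e, pos=e.pos + aln.ref_start))
                calls.append(VariantCall(read.read_id, e.pos, e.kind, e.ref, e.alt))
        write_calls_tsv(calls, path_out)
    else:
        raise ValueError(f"unsupported conversion {format_in} -> {format_out}")
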