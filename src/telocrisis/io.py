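"""Readers and writers for the pipeline's standard file formats.

BED is parsed as 0-based half-open; GFF3 coordinates (1-based closed) are
converted to the internal convention on read.  Calls round-trip exactly
through TSV; the BED export carries width-1 junction point intervals named
by event id for karyotype display.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrich import FeatureTrack
from .fusioncall import FusionCall, SubtelomereRef
from .reads import PairedReads

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(path, format: str | None = None,
                    name: str | None = None) -> FeatureTrack:
    """Read a BED or GFF3 file into a FeatureTrack.

    Format is inferred from the extension when not given.  Malformed lines
    raise with the offending line number; an empty file yields an empty
    track with a warning.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "GFF3" if suffix in (".gff", ".gff3") else "BED"
    format = format.upper()
    if format not in ("BED", "GFF3"):
        raise ValueError(f"unknown annotation format {format!r}")
    intervals, names, strands = [], [], []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if (not line.strip() or line.startswith("#")
                    or line.startswith(("track", "browser"))):
                continue
            fields = line.split("\t")
            try:
                if format == "BED":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    names.append(fields[3] if len(fields) > 3 else f"iv{ln}")
                    strands.append(fields[5] if len(fields) > 5 else ".")
                else:
                    chrom = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    names.append(_gff_attr(fields[8], "ID") or f"iv{ln}"
                                 if len(fields) > 8 else f"iv{ln}")
                    strands.append(fields[6] if len(fields) > 6 else ".")
                if start < 0 or end <= start:
                    raise ValueError("empty or negative interval")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{ln}: malformed {format} line "
                                 f"({exc})") from exc
            intervals.append((chrom, start, end))
    if not intervals:
        logger.warning("annotation file %s is empty", path)
    return FeatureTrack(name or path.stem, intervals, names=names,
                        strands=strands)


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def write_annotation_bed(track: FeatureTrack, path) -> None:
    with open(path, "w") as fh:
        for i, (chrom, s, e) in enumerate(track.intervals):
            nm = track.names[i] if track.names else f"iv{i}"
            fh.write(f"{chrom}\t{s}\t{e}\t{nm}\n")


# ---------------------------------------------------------------------------
# calls
# ---------------------------------------------------------------------------

_CALL_COLUMNS = ["call_id", "sample", "stage", "end_id", "subtel_breakpoint",
                 "partner_ref", "partner_pos", "partner_strand", "category",
                 "mh_bp", "ins_seq", "ins_templated", "deletion_a",
                 "deletion_b", "delta_deletion_bp", "support", "resolution"]


def write_calls(calls: list[FusionCall], path, format: str = "TSV") -> None:
    """Write calls as a TSV (round-trip exact) or BED of junction points."""
    format = format.upper()
    if format == "BED":
        with open(path, "w") as fh:
            for c in calls:
                chrom, pos, _ = c.partner
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{c.call_id}\n")
        return
    if format != "TSV":
        raise ValueError(f"unknown call format {format!r}")
    rows = []
    for c in calls:
        rows.append({
            "call_id": c.call_id, "sample": c.sample, "stage": c.stage,
            "end_id": c.end_id, "subtel_breakpoint": c.subtel_breakpoint,
            "partner_ref": c.partner[0], "partner_pos": c.partner[1],
            "partner_strand": c.partner[2], "category": c.category,
            "mh_bp": c.mh_bp, "ins_seq": c.ins_seq,
            "ins_templated": c.ins_templated if c.ins_templated else "NA",
            "deletion_a": c.deletion_bp[0],
            "deletion_b": c.deletion_bp[1] if c.deletion_bp[1] is not None else "NA",
            "delta_deletion_bp": c.delta_deletion_bp
            if c.delta_deletion_bp is not None else "NA",
            "support": c.support, "resolution": c.resolution,
        })
    pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls(path) -> list[FusionCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(FusionCall(
            sample=r["sample"], stage=r["stage"], end_id=r["end_id"],
            subtel_breakpoint=int(r["subtel_breakpoint"]),
            partner=(r["partner_ref"], int(r["partner_pos"]),
                     r["partner_strand"]),
            category=r["category"], mh_bp=int(r["mh_bp"]),
            ins_seq=r["ins_seq"],
            ins_templated=None if r["ins_templated"] == "NA" else r["ins_templated"],
            deletion_bp=(int(r["deletion_a"]),
                         None if r["deletion_b"] == "NA" else int(r["deletion_b"])),
            delta_deletion_bp=None if r["delta_deletion_bp"] == "NA"
            else int(r["delta_deletion_bp"]),
            support=int(r["support"]), resolution=r["resolution"],
            call_id=r["call_id"]))
    return out


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_subtel_meta(subtels: list[SubtelomereRef], path) -> None:
    """Sidecar TSV: end_id, family, archetype flag, primer/boundary, LTRs."""
    rows = [{
        "end_id": s.end_id, "family_id": s.family_id,
        "archetype": int(s.archetype), "primer_offset": s.primer_offset,
        "telomere_boundary": s.telomere_boundary,
        "ltr_intervals": ";".join(f"{a}-{b}" for a, b in s.ltr_intervals),
    } for s in subtels]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_subtelomeres(fasta_path, meta_path) -> list[SubtelomereRef]:
    seqs = read_fasta(fasta_path)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, r in meta.iterrows():
        ltr = tuple(tuple(map(int, p.split("-")))
                    for p in r["ltr_intervals"].split(";") if p)
        out.append(SubtelomereRef(
            end_id=r["end_id"], family_id=r["family_id"],
            sequence=seqs[r["end_id"]],
            primer_offset=int(r["primer_offset"]),
            telomere_boundary=int(r["telomere_boundary"]),
            ltr_intervals=ltr, archetype=bool(int(r["archetype"]))))
    return out


def write_fastq_pair(reads: PairedReads, prefix) -> tuple[Path, Path]:
    """Write mates to `<prefix>_R1.fastq` / `<prefix>_R2.fastq`."""
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_R1.fastq")
    p2 = prefix.with_name(prefix.name + "_R2.fastq")
    for path, seqs in ((p1, reads.r1), (p2, reads.r2)):
        records = []
        for rid, s in zip(reads.ids, seqs):
            rec = SeqRecord(Seq(s), id=rid, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(s)
            records.append(rec)
        SeqIO.write(records, str(path), "fastq")
    return p1, p2


def read_fastq_pair(path1, path2) -> PairedReads:
    reads = PairedReads()
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for rec1, rec2 in zip(it1, it2):
        reads.append(rec1.id, str(rec1.seq).upper(), str(rec2.seq).upper())
    return reads


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_truth(truth, path) -> None:
    rows = [{
        "id": t.id, "category": t.category, "end_id": t.end_id,
        "breakpoint": t.breakpoint, "partner_ref": t.partner[0],
        "partner_pos": t.partner[1], "partner_strand": t.partner[2],
        "partner_len": t.partner_len, "mh_bp": t.mh_bp, "ins_seq": t.ins_seq,
        "ins_templated": "NA" if t.ins_templated is None
        else str(bool(t.ins_templated)),
        "deletion_a": t.deletion_bp[0],
        "deletion_b": "NA" if t.deletion_bp[1] is None else t.deletion_bp[1],
    } for t in truth]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bin_counts(profile, dir_path) -> None:
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    profile.bins.to_csv(dir_path / "bins.tsv", sep="\t", index=False)
    profile.counts.to_csv(dir_path / "nuclei_counts.tsv", sep="\t")
    profile.bulk.to_frame("bulk").to_csv(dir_path / "bulk_counts.tsv", sep="\t")


def write_counts_matrix(matrix, dir_path) -> None:
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    matrix.counts.to_csv(dir_path / "counts.tsv", sep="\t")
    matrix.samples.to_csv(dir_path / "samples.tsv", sep="\t")
    if matrix.gene_intervals is not None:
        matrix.gene_intervals.to_csv(dir_path / "gene_intervals.tsv", sep="\t")
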