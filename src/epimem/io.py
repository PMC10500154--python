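"""Readers and writers for the on-disk formats.

Conventions: FASTA and GFF3 and allc-style methylation TSVs are 1-based
inclusive on disk; BED output is 0-based half-open; all internal
coordinates are 0-based half-open.  The conversions live only in this
module.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomeModel, cytosine_sites
from .methylome import MethylomeTable

ALLC_COLUMNS = ["chrom", "pos", "strand", "tri", "mc", "cov"]

_GFF_TYPE_MAP = {
    "gene": "gene",
    "dispersed_repeat": "dispersed_repeat",
    "transposable_element": "dispersed_repeat",
    "repeat_region": "dispersed_repeat",
    "pseudogene": "pseudogene",
}


# ----------------------------------------------------------------------
# FASTA


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ----------------------------------------------------------------------
# GFF3


def write_gff3(features: pd.DataFrame, path, chrom_lengths: dict[str, int] | None = None) -> None:
    """1-based inclusive GFF3; internal half-open intervals are converted."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for chrom, length in chrom_lengths.items():
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for _, f in features.iterrows():
            fh.write(
                f"{f['chrom']}\tepimem\t{f['type']}\t{f['start'] + 1}\t{f['end']}\t.\t"
                f"{f['strand']}\t.\tID={f['feature_id']}\n"
            )


def read_gff3(path, chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Features typed gene / dispersed_repeat / pseudogene, 0-based half-open.

    Unknown feature types are skipped with a warning; features beyond a
    provided chromosome length raise.
    """
    rows = []
    skipped: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in _GFF_TYPE_MAP:
                skipped.add(ftype)
                continue
            start, end = int(start) - 1, int(end)  # to 0-based half-open
            if start < 0 or end <= start:
                raise ValueError(f"{path}: line {lineno}: bad coordinates")
            if chrom_lengths is not None:
                if chrom not in chrom_lengths:
                    raise ValueError(f"{path}: line {lineno}: unknown sequence {chrom!r}")
                if end > chrom_lengths[chrom]:
                    raise ValueError(
                        f"{path}: line {lineno}: feature beyond {chrom} length"
                    )
            fid = ""
            for field in attrs.split(";"):
                if field.startswith("ID="):
                    fid = field[3:]
            rows.append((fid, chrom, start, end, strand, _GFF_TYPE_MAP[ftype]))
    if skipped:
        warnings.warn(f"skipped unknown GFF3 feature types: {sorted(skipped)}")
    return pd.DataFrame(
        rows, columns=["feature_id", "chrom", "start", "end", "strand", "type"]
    )


def read_genome(fasta_path, gff3_path, chloroplast: str | None = None) -> GenomeModel:
    sequences = read_fasta(fasta_path)
    lengths = {c: len(s) for c, s in sequences.items()}
    features = read_gff3(gff3_path, chrom_lengths=lengths)
    return GenomeModel(sequences=sequences, features=features, chloroplast=chloroplast)


# ----------------------------------------------------------------------
# allc-style methylation tables


def write_allc(table: MethylomeTable, sample_id: str, path) -> None:
    """Per-cytosine TSV: chrom, pos (1-based), strand, trinucleotide, mc, cov."""
    df = pd.DataFrame({
        "chrom": table.sites["chrom"].astype(str),
        "pos": table.sites["pos"] + 1,
        "strand": table.sites["strand"].astype(str),
        "tri": table.sites["tri"].astype(str),
        "mc": table.mc[sample_id],
        "cov": table.cov[sample_id],
    })
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(ALLC_COLUMNS) + "\t(pos is 1-based)\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_allc(path) -> pd.DataFrame:
    """Read one allc-style TSV into a frame with internal 0-based positions."""
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=ALLC_COLUMNS,
            dtype={"chrom": str, "strand": str, "tri": str},
        )
    except Exception as exc:  # surface the offending line if pandas knows it
        raise ValueError(f"{path}: malformed allc file: {exc}") from exc
    if len(df) == 0:
        return df.assign(pos=pd.Series(dtype=np.int64))
    for col in ("pos", "mc", "cov"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.astype("Int64").astype(float))
        if bad.any():
            lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # + header line
            raise ValueError(f"{path}: line {lineno}: non-integer {col!r}")
        df[col] = vals.astype(np.int64)
    bad = (df["mc"] < 0) | (df["mc"] > df["cov"])
    if bad.any():
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}: line {lineno}: mc > cov")
    if not df["strand"].isin(["+", "-"]).all():
        lineno = int(np.flatnonzero(~df["strand"].isin(["+", "-"]).to_numpy())[0]) + 2
        raise ValueError(f"{path}: line {lineno}: bad strand")
    df["pos"] -= 1  # to 0-based
    return df


def table_from_allc(design: pd.DataFrame, genome: GenomeModel) -> MethylomeTable:
    """Assemble a multi-sample table from per-sample allc files.

    ``design`` columns: sample, group, condition, replicate, path.  Sites
    are enumerated from the genome so that all samples align; allc rows at
    unknown positions raise.
    """
    sites = cytosine_sites(genome.sequences)
    table = MethylomeTable(sites)
    key = {}
    chrom_arr = sites["chrom"].astype(str).to_numpy()
    pos_arr = sites["pos"].to_numpy()
    strand_arr = sites["strand"].astype(str).to_numpy()
    for i in range(len(sites)):
        key[(chrom_arr[i], pos_arr[i], strand_arr[i])] = i
    for _, row in design.iterrows():
        df = read_allc(row["path"])
        mc = np.zeros(len(sites), dtype=np.int32)
        cov = np.zeros(len(sites), dtype=np.int32)
        for chrom, pos, strand, mcv, covv in zip(
            df["chrom"], df["pos"], df["strand"], df["mc"], df["cov"]
        ):
            idx = key.get((chrom, pos, strand))
            if idx is None:
                raise ValueError(
                    f"{row['path']}: site {chrom}:{pos + 1}:{strand} absent from genome"
                )
            mc[idx], cov[idx] = mcv, covv
        table.add_sample(row["sample"], mc, cov, group=row.get("group", ""),
                         condition=row.get("condition", ""),
                         replicate=int(row.get("replicate", 0)))
    return table


# ----------------------------------------------------------------------
# BED and design tables


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """DMRs as BED6+ (0-based half-open; score = level difference x 1000)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tcontext\tdirection"
                 "\tn_dms\tlevel_ctrl\tlevel_trt\t(BED: 0-based half-open)\n")
        for i, r in dmrs.iterrows():
            name = f"DMR_{r['context']}_{i + 1:05d}"
            score = int(round(abs(r["diff"]) * 1000))
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t{name}\t{score}\t.\t"
                f"{r['context']}\t{r['direction']}\t{r['n_dms']}\t"
                f"{r['level_ctrl']:.6f}\t{r['level_trt']:.6f}\n"
            )


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "group", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["group", "condition", "replicate"])
    if dup.any():
        raise ValueError("duplicate (group, condition, replicate) in design")
    if "path" in df.columns:
        for p in df["path"]:
            if not Path(p).exists():
                raise FileNotFoundError(f"design references missing file {p}")
    return df


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)
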