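"""File-format plumbing: FASTA/FASTQ via Biopython, BED/TSV/CSV via pandas.

Coordinates are 0-based half-open everywhere, matching BED.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidParameterError
from .feature_annotation import FeatureSet
from .is_calling import IntegrationSite
from .read_processing import RawRead


def write_fastq(reads, path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        qual = r.quality or "I" * len(r.sequence)
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def read_fastq(path) -> list[RawRead]:
    out = []
    for rec in SeqIO.parse(path, "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(RawRead(rec.id, str(rec.seq).upper(), qual))
    return out


def write_genome_fasta(genome, path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.chromosomes],
        path,
        "fasta",
    )


def read_genome_fasta(path):
    from .synthetic import ToyGenome

    chroms = tuple(
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")
    )
    if not chroms:
        raise InvalidParameterError(f"no sequences in {path}")
    return ToyGenome(chroms)


# ---------------------------------------------------------------------------
# BED


def write_feature_bed(features: FeatureSet | list[FeatureSet], path) -> None:
    """BED4: chrom, start, end, label."""
    sets = [features] if isinstance(features, FeatureSet) else list(features)
    rows = [(c, s, e, fs.label) for fs in sets for c, s, e in fs.intervals]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_feature_bed(path) -> dict[str, FeatureSet]:
    """Read a BED file with the class label in column 4; one FeatureSet per
    label."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise InvalidParameterError("feature BED needs >= 4 columns (label in col 4)")
    df.columns = ["chrom", "start", "end", "label"] + [
        f"c{i}" for i in range(4, df.shape[1])
    ]
    return {
        str(label): FeatureSet(str(label), list(zip(sub["chrom"], sub["start"], sub["end"])))
        for label, sub in df.groupby("label")
    }


def read_chromhmm_table(path) -> dict[str, FeatureSet]:
    """UCSC chromHMM segmentation table dialect: bin, chrom, start, end, name."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 5:
        raise InvalidParameterError("chromHMM table needs 5 columns")
    df = df.iloc[:, :5]
    df.columns = ["bin", "chrom", "start", "end", "name"]
    return {
        str(label): FeatureSet(str(label), list(zip(sub["chrom"], sub["start"], sub["end"])))
        for label, sub in df.groupby("name")
    }


def write_sites_bed(sites: list[IntegrationSite], path) -> None:
    """6-column BED: chrom, pos, pos+1, name, read_support, strand."""
    rows = [
        (s.chrom, s.position, s.position + 1, f"IS_{i}", s.read_support, s.strand)
        for i, s in enumerate(sites)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_sites_bed(path) -> pd.DataFrame:
    """Site table (chrom, position, strand[, read_support]) from 6-column BED."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise InvalidParameterError("site BED needs 6 columns")
    out = pd.DataFrame(
        {
            "chrom": df.iloc[:, 0],
            "position": df.iloc[:, 1].astype(int),
            "strand": df.iloc[:, 5],
            "read_support": df.iloc[:, 4].astype(int),
        }
    )
    return out


def write_flanks_fastq(trimmed, path) -> None:
    write_fastq(
        [RawRead(t.id, t.flank, "I" * len(t.flank)) for t in trimmed], path
    )
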