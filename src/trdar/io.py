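"""Readers and writers for the standard formats shared by all modules.

Internal coordinates are 0-based half-open (BED native); GFF3 is converted
on read and write (1-based inclusive).  Result tables are TSV with
``#``-prefixed metadata header lines.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .annotation import GeneModel
from .intervals import GenomicInterval, RegionSet


class DataError(ValueError):
    """Malformed input data (CLI exit code 3)."""


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------


def read_bed(path) -> RegionSet:
    """Read BED3/BED4/BED6 into a RegionSet (4th column = id when present)."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                if len(f) < 3:
                    raise ValueError("fewer than 3 columns")
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 and f[3] not in (".", "") else None
                strand = f[5] if len(f) > 5 and f[5] in "+-." else "."
                regions.append(
                    GenomicInterval(chrom, start, end, strand=strand, id=name)
                )
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
    return RegionSet(regions)


def write_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\t0\t{r.strand}\n")


def read_state_bed(path) -> pd.DataFrame:
    """Chromatin-state BED: 4th column is the state label."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            try:
                if len(f) < 4:
                    raise ValueError("state BED needs 4 columns")
                rows.append((f[0], int(f[1]), int(f[2]), f[3]))
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: malformed state BED: {exc}") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def write_state_bed(states: pd.DataFrame, path) -> None:
    states[["chrom", "start", "end", "state"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_narrowpeak(path) -> RegionSet:
    """ENCODE narrowPeak (BED6+4); the 4th column provides ids."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if len(f) < 10:
                    raise ValueError("narrowPeak needs 10 columns")
                regions.append(
                    GenomicInterval(
                        f[0],
                        int(f[1]),
                        int(f[2]),
                        strand=f[5] if f[5] in "+-." else ".",
                        id=f[3] if f[3] != "." else None,
                    )
                )
            except ValueError as exc:
                raise DataError(
                    f"{path}:{lineno}: malformed narrowPeak line: {exc}"
                ) from exc
    return RegionSet(regions)


# ---------------------------------------------------------------------------
# gene models: GFF3 and BED12
# ---------------------------------------------------------------------------


def read_gff3(path) -> List[GeneModel]:
    """Gene models from GFF3 (converted to 0-based half-open on read)."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons, utr5, utr3 = [], [], []
        for child in db.children(g):
            iv = (child.start - 1, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(iv)
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                gene_span=(g.start - 1, g.end),
                exons=tuple(sorted(exons)),
                five_prime_utrs=tuple(sorted(utr5)),
                three_prime_utrs=tuple(sorted(utr3)),
            )
        )
    if not genes:
        raise DataError(f"{path}: no gene features found")
    return genes


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.gene_span
            fh.write(
                f"{g.chrom}\tsim\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsim\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}\n"
                )
            for i, (xs, xe) in enumerate(g.five_prime_utrs, 1):
                fh.write(
                    f"{g.chrom}\tsim\tfive_prime_UTR\t{xs + 1}\t{xe}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.u5{i};Parent={g.gene_id}\n"
                )
            for i, (xs, xe) in enumerate(g.three_prime_utrs, 1):
                fh.write(
                    f"{g.chrom}\tsim\tthree_prime_UTR\t{xs + 1}\t{xe}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.u3{i};Parent={g.gene_id}\n"
                )


def read_bed12(path) -> List[GeneModel]:
    """Gene models from BED12; UTRs derived from the thick (CDS) bounds."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            try:
                if len(f) < 12:
                    raise ValueError("BED12 needs 12 columns")
                chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
                strand = f[5]
                thick_s, thick_e = int(f[6]), int(f[7])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple(
                    (start + off, start + off + sz)
                    for off, sz in zip(starts, sizes)
                )
                utr5, utr3 = [], []
                for xs, xe in exons:
                    left = (max(xs, start), min(xe, thick_s))
                    right = (max(xs, thick_e), min(xe, end))
                    if left[0] < left[1]:
                        (utr5 if strand == "+" else utr3).append(left)
                    if right[0] < right[1]:
                        (utr3 if strand == "+" else utr5).append(right)
                genes.append(
                    GeneModel(
                        gene_id=name,
                        chrom=chrom,
                        strand=strand,
                        gene_span=(start, end),
                        exons=exons,
                        five_prime_utrs=tuple(sorted(utr5)),
                        three_prime_utrs=tuple(sorted(utr3)),
                    )
                )
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: malformed BED12 line: {exc}") from exc
    return genes


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# TSV tables with metadata headers
# ---------------------------------------------------------------------------


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path, metadata: Optional[Mapping[str, object]] = None
) -> None:
    """TSV with '#'-prefixed metadata lines (tool version always included)."""
    meta = {"tool_version": __version__}
    meta.update(metadata or {})
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_counts(counts: pd.DataFrame, path, metadata=None) -> None:
    write_table(counts.rename_axis("feature_id").reset_index(), path, metadata)


def read_counts(path) -> pd.DataFrame:
    return read_table(path).set_index("feature_id")


def read_differential(path) -> pd.DataFrame:
    df = read_table(path)
    required = ["feature_id", "log2fc", "p", "fdr", "direction"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing differential columns {missing}")
    return df[required]


def read_survival_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in ("time", "event", "group"):
        if col not in df.columns:
            raise DataError(f"{path}: survival CSV needs a {col!r} column")
    return df


def write_survival_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_gene_sets(path) -> Dict[str, set]:
    """GMT-style TSV: set name, description, then member genes."""
    sets: Dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise DataError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[f[0]] = set(x for x in f[2:] if x)
    return sets


def write_gene_sets(sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t-\t{members}\n")
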